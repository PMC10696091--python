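"""Generator contracts: determinism, composition targets, shotgun model,
confounding and hazard wiring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microseek import simulate as sim
from microseek.outcomes import logrank_test


class TestOriginModels:
    def test_invalid_transition_rejected(self):
        bad = np.full((16, 4), 0.3)
        with pytest.raises(ValueError):
            sim.OriginModel("human", bad)

    def test_stationary_gc_matches_target(self, origin_models):
        for label, target in (("human", 0.50), ("viral", 0.40), ("bacterial", 0.65)):
            assert origin_models[label].stationary_gc() == pytest.approx(target, abs=1e-3)

    def test_realized_gc_on_long_sequence(self, origin_models):
        # bacterial target 0.65; realized GC on 10 kb within +-0.03
        seq = sim.sample_sequence(origin_models["bacterial"], 10_000, np.random.default_rng(2))
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.65, abs=0.03)


class TestMakeReferences:
    def test_empty_and_deterministic(self, origin_models):
        assert sim.make_references(origin_models, 0, (500, 600), 1) == []
        a = sim.make_references(origin_models, 5, (500, 900), 7)
        b = sim.make_references(origin_models, 5, (500, 900), 7)
        assert sim.references_to_fasta(a) == sim.references_to_fasta(b)

    def test_labels_and_taxa(self, origin_models):
        refs = sim.make_references(origin_models, 6, (500, 900), 1, n_genera=3)
        assert {r.label for r in refs} == {"human", "viral", "bacterial"}
        bacterial = [r for r in refs if r.label == "bacterial"]
        assert all(r.genus for r in bacterial)
        assert len({r.genus for r in bacterial}) == 3

    def test_fasta_round_trip(self, origin_models):
        refs = sim.make_references(origin_models, 3, (500, 700), 9)
        again = sim.references_from_fasta(sim.references_to_fasta(refs))
        assert again == refs


class TestMakeReads:
    def _refs(self, origin_models):
        return sim.make_references(origin_models, 4, (760, 761), rng_seed=3)

    def test_zero_coverage_zero_host_is_empty(self, origin_models):
        refs = self._refs(origin_models)
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(refs[0].accession, 0.0)])
        reads, truth = sim.make_reads(spec, refs)
        assert reads == [] and truth.empty

    def test_no_n_when_rate_zero(self, origin_models):
        refs = self._refs(origin_models)
        acc = [r for r in refs if r.label == "bacterial"][0].accession
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(acc, 5.0)], n_rate=0.0, rng_seed=4)
        reads, _ = sim.make_reads(spec, refs)
        assert reads and all("N" not in r.sequence for r in reads)

    def test_poisson_read_count(self, origin_models):
        # transcript length 760, read length 76, coverage 10 -> 100 +- 30 reads
        refs = self._refs(origin_models)
        acc = [r for r in refs if r.label == "bacterial"][0].accession
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(acc, 10.0)], read_length=76, rng_seed=5)
        reads, _ = sim.make_reads(spec, refs)
        assert 70 <= len(reads) <= 130

    def test_reads_are_substrings_at_truth_positions(self, origin_models):
        refs = self._refs(origin_models)
        by_acc = {r.accession: r for r in refs}
        acc = [r for r in refs if r.label == "viral"][0].accession
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(acc, 3.0)], host_read_count=20, rng_seed=6)
        reads, truth = sim.make_reads(spec, refs)
        seqs = {r.read_id: r.sequence for r in reads}
        for row in truth.itertuples(index=False):
            expected = by_acc[row.accession].sequence[row.position : row.position + 75]
            got = seqs[row.read_id]
            assert all(a == b or b == "N" for a, b in zip(expected, got))

    def test_coverage_tiles_transcript_interior(self, origin_models):
        # at coverage >= 20 every interior position is covered; the first and
        # last read-length bases are boundary-limited under uniform starts
        refs = self._refs(origin_models)
        ref = [r for r in refs if r.label == "bacterial"][0]
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(ref.accession, 20.0)], rng_seed=7)
        _, truth = sim.make_reads(spec, refs)
        cover = np.zeros(len(ref.sequence), dtype=int)
        for pos in truth["position"]:
            cover[pos : pos + 75] += 1
        assert (cover[75:-75] > 0).all()

    def test_missing_accession_raises(self, origin_models):
        refs = self._refs(origin_models)
        spec = sim.SampleSpec("S0", "P0", "case", planted=[("NOPE_0001", 1.0)])
        with pytest.raises(KeyError):
            sim.make_reads(spec, refs)

    def test_fastq_round_trip(self, origin_models):
        refs = self._refs(origin_models)
        acc = refs[0].accession
        spec = sim.SampleSpec("S0", "P0", "case", planted=[(acc, 2.0)], n_rate=0.01, rng_seed=8)
        reads, _ = sim.make_reads(spec, refs)
        assert sim.reads_from_fastq(sim.reads_to_fastq(reads)) == reads


class TestMakeCohort:
    def test_null_effects_give_identical_distributions(self):
        cov, _ = sim.make_cohort(sim.CohortSpec(250, 250, {}, {}, 0.2, rng_seed=1))
        case = cov[cov.cohort == "case"]
        ctrl = cov[cov.cohort == "control"]
        for c in ("age", "weight", "seq_depth"):
            assert stats.ks_2samp(case[c], ctrl[c]).pvalue > 0.01

    def test_logrank_type_one_near_nominal_for_null_feature(self):
        # feature with zero log hazard ratio: rejection near alpha
        rng = np.random.default_rng(2)
        rej = []
        for rep in range(500):
            pres = pd.DataFrame({"F": rng.random(60) < 0.5},
                                index=[f"P{i:04d}" for i in range(60)])
            _, surv = sim.make_cohort(
                sim.CohortSpec(30, 30, {}, {"F": 0.0}, 0.2, rng_seed=10_000 + rep), pres)
            os = surv[surv.endpoint == "OS"].set_index("patient_id").loc[pres.index]
            if pres["F"].sum() in (0, 60):
                continue
            _, p = logrank_test(os["time"], os["event"], pres["F"])
            rej.append(p < 0.05)
        assert 0.02 <= np.mean(rej) <= 0.09

    def test_logrank_power_for_strong_hazard(self):
        # log HR = log 3, n = 200/arm, censoring 0.2: reject in > 90% of reps
        rej = []
        for rep in range(60):
            pres = pd.DataFrame({"F": [True] * 200 + [False] * 200},
                                index=[f"P{i:04d}" for i in range(400)])
            _, surv = sim.make_cohort(
                sim.CohortSpec(200, 200, {}, {"F": float(np.log(3))}, 0.2, rng_seed=20_000 + rep), pres)
            os = surv[surv.endpoint == "OS"].set_index("patient_id").loc[pres.index]
            _, p = logrank_test(os["time"], os["event"], pres["F"])
            rej.append(p < 0.05)
        assert np.mean(rej) > 0.9

    def test_unknown_feature_in_hazard_raises(self):
        pres = pd.DataFrame({"F": [True, False]}, index=["P0000", "P0001"])
        with pytest.raises(ValueError):
            sim.make_cohort(sim.CohortSpec(1, 1, {}, {"G": 1.0}, 0.2, 0), pres)

    def test_confounding_is_learnable(self):
        # nonzero covariate effects must yield propensity AUROC > 0.7
        from microseek.cohort import IPWConfig, fit_propensity

        cov, _ = sim.make_cohort(sim.CohortSpec(250, 250, {"age": 1.0, "seq_depth": 0.8}, {}, 0.2, 3))
        _, auc = fit_propensity(cov, cov["cohort"], IPWConfig(rng_seed=0))
        assert auc > 0.7

    def test_confounded_null_feature_tracks_covariate(self):
        cov, _ = sim.make_cohort(sim.CohortSpec(400, 400, {}, {}, 0.2, 4))
        f = sim.confounded_null_feature(cov, "age", slope=2.0, rng=5)
        old = cov["age"] > cov["age"].median()
        assert f[old].mean() > f[~old].mean() + 0.2
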