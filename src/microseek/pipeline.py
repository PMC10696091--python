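"""End-to-end orchestration: simulate -> host-filter -> score -> assemble ->
annotate -> cohort statistics, from one config, fully deterministic per seed.

The host-read pre-filter removes reads with an exact full-length match (on
either strand) to the human-labeled references.  On synthetic data the
origin classes are disjoint by construction, so exact matching plays the
role an external human-genome aligner plays on real data; a real deployment
would plug an aligner in behind the same interface.

One root seed fans out to per-stage child seeds (see :mod:`microseek.seeding`)
so a stage re-run in isolation reproduces its in-pipeline behavior, and two
identical runs produce byte-identical result tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, simulate as sim
from .annotation import (
    AnnotationHit,
    NucleotideDB,
    NucleotideRecord,
    ProteinDB,
    ProteinRecord,
    blast_nucleotide_search,
    nucleotide_search,
    pool_to_family,
    pool_to_genus,
    screen_contaminants,
    translated_search,
    hits_to_table,
)
from .assembly import AssemblyParams, ScoredRead, assemble_sample, contigs_to_fasta, membership_table
from .classifier import TrainedClassifier, score_reads, train_classifier
from .cohort import IPWConfig, PresenceMatrix, build_matrix, ipw_analysis, prevalence_analysis
from .network import ClassifierConfig
from .outcomes import survival_screen
from .seeding import child_seed
from .segmentation import SegmentationConfig, build_dataset


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulateConfig:
    n_case: int = 10
    n_control: int = 10
    n_per_class: int = 24
    n_genera: int = 3
    length_range: tuple[int, int] = (500, 1100)
    read_length: int = 75
    n_rate: float = 0.005
    coverage: float = 20.0
    host_reads_per_sample: int = 150
    case_genus_prob: float = 0.8  # case-enriched genus planting probability in cases
    control_genus_prob: float = 0.2
    background_prob: float = 0.5
    survival_feature_prob: float = 0.5
    covariate_effects: dict[str, float] = field(default_factory=lambda: {"age": 1.0, "seq_depth": 1.0})
    survival_log_hr: float = float(np.log(3.0))
    censoring_rate: float = 0.2
    dual_sample_patients: int = 2  # patients contributing two samples (OR pooling)


@dataclass
class PipelineConfig:
    out_dir: str = "microseek_out"
    rng_seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(stride_by_class={"human": 10, "viral": 10, "bacterial": 10})
    )
    classifier: ClassifierConfig = field(default_factory=lambda: ClassifierConfig(epochs=5))
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    ipw: IPWConfig = field(default_factory=IPWConfig)
    e_max_nt: float = 0.01
    e_max_prot: float = 1e-5
    min_prevalence: float = 0.10
    contaminants: list[str] = field(default_factory=list)
    annotation_backend: str = "builtin"  # builtin | blast
    run_assembly: bool = True
    run_annotation: bool = True
    run_stats: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (
            ("simulate", SimulateConfig),
            ("segmentation", SegmentationConfig),
            ("classifier", ClassifierConfig),
            ("assembly", AssemblyParams),
            ("ipw", IPWConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                block = kwargs[key]
                if key == "simulate" and "length_range" in block:
                    block["length_range"] = tuple(block["length_range"])
                if key == "segmentation" and "split_fractions" in block:
                    block["split_fractions"] = tuple(block["split_fractions"])
                kwargs[key] = sub(**block)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Study fixture
# ---------------------------------------------------------------------------


@dataclass
class StudyFixture:
    references: list[sim.ReferenceRecord]
    nt_db: NucleotideDB
    prot_db: ProteinDB
    samples: list[sim.SampleSpec]
    reads: dict[str, list[sim.ReadRecord]]
    truth: pd.DataFrame  # read-level truth
    sample_to_patient: dict[str, str]
    cohort_labels: dict[str, str]
    truth_genus: pd.DataFrame  # planted genus presence per patient
    truth_family: pd.DataFrame  # planted protein-family presence per patient
    covariates: pd.DataFrame
    survival: pd.DataFrame
    case_genus: str
    survival_family: str


def _protein_window(ref: sim.ReferenceRecord, length_nt: int = 300) -> str:
    """In-frame window starting at 0, translated; the contig encoding it is
    an exact translated-search hit."""
    from Bio.Seq import Seq

    sub = ref.sequence[: length_nt - (length_nt % 3)]
    return str(Seq(sub).translate())


def simulate_study(config: SimulateConfig, rng_seed: int) -> StudyFixture:
    """Generate the full synthetic study a pipeline run needs."""
    models = sim.divergent_origin_models(child_seed(rng_seed, "models"))
    refs = sim.make_references(
        models, config.n_per_class, config.length_range,
        rng_seed=child_seed(rng_seed, "references"), n_genera=config.n_genera,
    )
    bacterial = [r for r in refs if r.label == "bacterial"]
    viral = [r for r in refs if r.label == "viral"]
    genera = sorted({r.genus for r in bacterial})
    case_genus = genera[0]

    nt_db = NucleotideDB(
        [
            NucleotideRecord(r.accession, r.sequence, r.species, r.genus,
                             "bacterial" if r.label == "bacterial" else "viral_reference")
            for r in refs if r.label != "human"
        ]
    )
    # protein DB: in-frame windows of bacterial transcripts, one family each
    surv_ref = bacterial[1]  # the survival-linked transcript
    prot_records = [
        ProteinRecord(f"WP_{i:07d}.1", _protein_window(r), f"FAM_{r.accession}")
        for i, r in enumerate(bacterial[: max(8, 2)])
    ]
    prot_db = ProteinDB(prot_records)
    survival_family = f"FAM_{surv_ref.accession}"

    by_genus: dict[str, list[sim.ReferenceRecord]] = {}
    for r in bacterial:
        by_genus.setdefault(r.genus, []).append(r)

    rng = np.random.default_rng(child_seed(rng_seed, "planting"))
    n_patients = config.n_case + config.n_control
    patient_ids = [f"P{i:04d}" for i in range(n_patients)]
    cohorts = ["case"] * config.n_case + ["control"] * config.n_control
    cohort_labels = dict(zip(patient_ids, cohorts))

    samples: list[sim.SampleSpec] = []
    sample_to_patient: dict[str, str] = {}
    reads: dict[str, list[sim.ReadRecord]] = {}
    truth_frames = []
    genus_truth = pd.DataFrame(False, index=patient_ids, columns=genera)
    family_truth = pd.DataFrame(False, index=patient_ids, columns=[survival_family])

    serial = 0
    for pid, cohort in zip(patient_ids, cohorts):
        n_samples = 2 if int(pid[1:]) < config.dual_sample_patients else 1
        # patient-level planting decisions (shared across that patient's samples)
        planted_accs: list[str] = []
        p_enriched = config.case_genus_prob if cohort == "case" else config.control_genus_prob
        for genus in genera:
            prob = p_enriched if genus == case_genus else config.background_prob
            if rng.random() < prob:
                pool = by_genus[genus]
                planted_accs.append(pool[int(rng.integers(len(pool)))].accession)
                genus_truth.loc[pid, genus] = True
        if rng.random() < config.survival_feature_prob:
            planted_accs.append(surv_ref.accession)
            family_truth.loc[pid, survival_family] = True
            genus_truth.loc[pid, surv_ref.genus] = True
        if rng.random() < 0.3 and viral:
            planted_accs.append(viral[int(rng.integers(len(viral)))].accession)
        planted_accs = sorted(set(planted_accs))

        for _ in range(n_samples):
            sid = f"S{serial:04d}"
            serial += 1
            spec = sim.SampleSpec(
                sample_id=sid, patient_id=pid, cohort=cohort,
                planted=[(a, config.coverage) for a in planted_accs],
                read_length=config.read_length, n_rate=config.n_rate,
                host_read_count=config.host_reads_per_sample,
                rng_seed=child_seed(rng_seed, f"reads:{sid}"),
            )
            samples.append(spec)
            sample_to_patient[sid] = pid
            r, t = sim.make_reads(spec, refs)
            reads[sid] = r
            t.insert(0, "sample_id", sid)
            truth_frames.append(t)

    cohort_spec = sim.CohortSpec(
        n_case=config.n_case, n_control=config.n_control,
        covariate_effects=config.covariate_effects,
        feature_hazard={survival_family: config.survival_log_hr},
        censoring_rate=config.censoring_rate,
        rng_seed=child_seed(rng_seed, "cohort"),
    )
    covariates, survival = sim.make_cohort(cohort_spec, family_truth)

    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames else pd.DataFrame()
    return StudyFixture(
        refs, nt_db, prot_db, samples, reads, truth, sample_to_patient, cohort_labels,
        genus_truth, family_truth, covariates, survival, case_genus, survival_family,
    )


# ---------------------------------------------------------------------------
# Host filtering
# ---------------------------------------------------------------------------


def filter_host_reads(
    reads: list[sim.ReadRecord], host_references: list[sim.ReferenceRecord]
) -> tuple[list[sim.ReadRecord], int]:
    """Drop reads exactly matching a host reference (either strand), full length.

    Returns (retained reads, number removed).  With no host reference all
    reads are retained.
    """
    from .aligner import revcomp

    host = [r.sequence for r in host_references if r.label == "human"]
    if not host:
        return list(reads), 0
    haystack = "#".join(host + [revcomp(s) for s in host])
    kept = [r for r in reads if r.sequence not in haystack]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    out_dir: Path
    report: dict
    presence_genus: PresenceMatrix | None = None
    presence_family: PresenceMatrix | None = None
    results: dict[str, pd.DataFrame] = field(default_factory=dict)
    model: TrainedClassifier | None = None


def _write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full flow and write every stage output under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    counts: dict[str, int] = {}

    # --- stage: simulate ---------------------------------------------------
    study = simulate_study(config.simulate, seed)
    _write(out / "references.fasta", sim.references_to_fasta(study.references))
    for spec in study.samples:
        _write(out / "reads" / f"{spec.sample_id}.fastq", sim.reads_to_fastq(study.reads[spec.sample_id]))
    _write_tsv(out / "covariates.tsv", study.covariates, index=True)
    _write_tsv(out / "survival.tsv", study.survival)
    counts["samples"] = len(study.samples)
    counts["reads_in"] = sum(len(v) for v in study.reads.values())

    # --- stage: train classifier ------------------------------------------
    datasets = build_dataset(study.references, config.segmentation, child_seed(seed, "split"))
    clf_cfg = ClassifierConfig(**{**asdict(config.classifier), "rng_seed": child_seed(seed, "train")})
    model = train_classifier(datasets, clf_cfg)
    counts["train_segments"] = len(datasets.train)

    # --- stage: host filter + score ----------------------------------------
    host_refs = [r for r in study.references if r.label == "human"]
    score_tables: dict[str, pd.DataFrame] = {}
    scored_pool: dict[str, list[ScoredRead]] = {}
    counts["reads_host_filtered"] = 0
    counts["reads_excluded_N"] = 0
    counts["reads_scored"] = 0
    for spec in study.samples:
        sid = spec.sample_id
        retained, n_host = filter_host_reads(study.reads[sid], host_refs)
        counts["reads_host_filtered"] += n_host
        rng = np.random.default_rng(child_seed(seed, f"score:{sid}"))
        table, norm = score_reads(model, retained, rng)
        counts["reads_excluded_N"] += int(table["excluded"].sum())
        counts["reads_scored"] += int((~table["excluded"]).sum())
        score_tables[sid] = table
        seqs = {r.read_id: r.sequence for r in retained}
        repl = {rid: nr.n_replacement for rid, nr in norm.items() if nr.n_replacement}
        scored_pool[sid] = [
            ScoredRead(row.read_id, seqs[row.read_id], float(row.p_bacterial),
                       float(row.p_viral), repl.get(row.read_id))
            for row in table.itertuples(index=False) if not bool(row.excluded)
        ]
        _write_tsv(out / "scores" / f"{sid}.tsv", table)

    if not config.run_assembly:
        report = _finalize_report(config, counts, out)
        return PipelineResult(out, report, model=model)

    # --- stage: assemble ----------------------------------------------------
    contigs_by_sample = {}
    counts["seeds"] = 0
    counts["contigs"] = 0
    from .assembly import select_and_sort_seeds

    for spec in study.samples:
        sid = spec.sample_id
        counts["seeds"] += len(select_and_sort_seeds(scored_pool[sid], config.assembly.seed_threshold))
        contigs = assemble_sample(scored_pool[sid], config.assembly)
        contigs_by_sample[sid] = contigs
        counts["contigs"] += len(contigs)
        _write(out / "contigs" / f"{sid}.fasta", contigs_to_fasta(contigs))
        _write_tsv(out / "contigs" / f"{sid}.members.tsv", membership_table(contigs))

    if not config.run_annotation:
        report = _finalize_report(config, counts, out)
        return PipelineResult(out, report, model=model)

    # --- stage: annotate ----------------------------------------------------
    nt_search = blast_nucleotide_search if config.annotation_backend == "blast" else nucleotide_search
    genus_rows, family_rows = [], []
    all_nt_hits: list[AnnotationHit] = []
    all_prot_hits: list[AnnotationHit] = []
    for spec in study.samples:
        sid = spec.sample_id
        # only multi-read or seed contigs are searched; all contigs qualify here
        nt_hits = nt_search(contigs_by_sample[sid], study.nt_db, config.e_max_nt)
        nt_hits, _removed = screen_contaminants(nt_hits, config.contaminants)
        prot_hits = translated_search(contigs_by_sample[sid], study.prot_db, config.e_max_prot)
        for h in nt_hits + prot_hits:
            h.contig_id = f"{sid}:{h.contig_id}"
        all_nt_hits.extend(nt_hits)
        all_prot_hits.extend(prot_hits)
        genus_rows.append({"sample_id": sid, **{g: True for g in pool_to_genus(nt_hits)}})
        family_rows.append({"sample_id": sid, **{f: True for f in pool_to_family(prot_hits)}})
    counts["nt_hits"] = len(all_nt_hits)
    counts["prot_hits"] = len(all_prot_hits)
    _write_tsv(out / "hits_nucleotide.tsv", hits_to_table(all_nt_hits))
    _write_tsv(out / "hits_protein.tsv", hits_to_table(all_prot_hits))

    def presence_df(rows, columns) -> pd.DataFrame:
        df = pd.DataFrame(rows).set_index("sample_id").reindex(columns=sorted(columns))
        return df.notna() & df.astype(object).eq(True)

    genus_cols = sorted({g for r in genus_rows for g in r if g != "sample_id"})
    family_cols = sorted({f for r in family_rows for f in r if f != "sample_id"})
    presence_genus = build_matrix(
        presence_df(genus_rows, genus_cols), study.sample_to_patient, study.cohort_labels, "genus"
    )
    presence_family = build_matrix(
        presence_df(family_rows, family_cols), study.sample_to_patient, study.cohort_labels, "protein"
    )
    _write_tsv(out / "presence_genus.tsv", presence_genus.data, index=True)
    _write_tsv(out / "presence_protein.tsv", presence_family.data, index=True)

    result = PipelineResult(out, {}, presence_genus, presence_family, model=model)
    if not config.run_stats:
        result.report = _finalize_report(config, counts, out)
        return result

    # --- stage: statistics ---------------------------------------------------
    results: dict[str, pd.DataFrame] = {}
    results["binomial"] = prevalence_analysis(presence_genus, config.min_prevalence)
    ipw_cfg = IPWConfig(**{**asdict(config.ipw), "rng_seed": child_seed(seed, "ipw")})
    ipw_table, auc = ipw_analysis(presence_genus, study.covariates, ipw_cfg)
    results["ipw"] = ipw_table
    combined = PresenceMatrix(
        presence_genus.data.join(presence_family.data, how="outer").astype(object).eq(True),
        presence_genus.cohort, "mixed",
    )
    results["survival"] = survival_screen(combined, study.survival)
    for name, df in results.items():
        _write_tsv(out / f"results_{name}.tsv", df)
    counts["features_binomial"] = len(results["binomial"])
    counts["features_ipw"] = len(results["ipw"])
    counts["features_survival_tested"] = int(results["survival"]["tested"].sum())
    counts["propensity_auc_x1000"] = int(round(auc * 1000))

    result.results = results
    result.report = _finalize_report(config, counts, out)
    return result


def _finalize_report(config: PipelineConfig, counts: dict[str, int], out: Path) -> dict:
    report = {
        "version": __version__,
        "rng_seed": config.rng_seed,
        "counts": dict(sorted(counts.items())),
    }
    _write(out / "report.json", json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
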