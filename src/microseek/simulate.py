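"""Synthetic fixtures: origin models, references, reads, cohorts, survival.

Real inputs for this problem (tumor and healthy-tissue RNA-seq, patient
covariates) are access-controlled, so every other module is exercised on
synthetic data built here.  Origin classes (human / viral / bacterial) are
emulated as order-2 Markov chains over {A,C,G,T} with well-separated
transition structure — a learnable compositional signal analogous to genome
k-mer signatures.  Reads follow a standard shotgun model: Poisson counts per
transcript, uniform positions, optional per-base N corruption.  Cohort
covariates are drawn with cohort-dependent shifts (confounding by
construction) and survival times are exponential with hazards that depend on
designated microbial features.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
ORIGIN_LABELS = ("human", "viral", "bacterial")

# ---------------------------------------------------------------------------
# Origin models
# ---------------------------------------------------------------------------


@dataclass
class OriginModel:
    """Order-2 Markov source over {A,C,G,T}.

    ``transition`` has shape (16, 4): row index is the previous dinucleotide
    context ``4*b1 + b2`` (bases in A,C,G,T order), columns are the next-base
    probabilities.  Every row must sum to 1 within 1e-9.
    """

    label: str
    transition: np.ndarray
    gc_target: float = 0.5

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (16, 4):
            raise ValueError(f"transition must be (16, 4), got {t.shape}")
        if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must be non-negative and sum to 1")
        self.transition = t

    def stationary_context(self) -> np.ndarray:
        """Stationary distribution over the 16 dinucleotide contexts."""
        # context (b1,b2) -> (b2, next)
        m = np.zeros((16, 16))
        for ctx in range(16):
            b2 = ctx % 4
            for nxt in range(4):
                m[ctx, 4 * b2 + nxt] += self.transition[ctx, nxt]
        vals, vecs = np.linalg.eig(m.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def stationary_gc(self) -> float:
        pi = self.stationary_context()
        return float(pi.reshape(4, 4)[:, [1, 2]].sum())


def _tilted_transition(raw: np.ndarray, tilt: float) -> np.ndarray:
    w = raw.copy()
    w[:, 1] *= tilt  # C
    w[:, 2] *= tilt  # G
    return w / w.sum(axis=1, keepdims=True)


def _calibrate_gc(raw: np.ndarray, label: str, gc_target: float) -> OriginModel:
    """Bisection on a G/C column tilt until stationary GC hits the target."""
    lo, hi = 1e-3, 1e3
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        model = OriginModel(label, _tilted_transition(raw, mid), gc_target)
        if model.stationary_gc() < gc_target:
            lo = mid
        else:
            hi = mid
    return OriginModel(label, _tilted_transition(raw, np.sqrt(lo * hi)), gc_target)


def divergent_origin_models(
    rng_seed: int = 0,
    gc_targets: dict[str, float] | None = None,
    sharpness: float = 1.3,
) -> dict[str, OriginModel]:
    """Build three well-separated order-2 Markov sources.

    Each class gets its own random context->preferred-base map; the preferred
    base receives ``exp(sharpness)`` times the weight of the others, then the
    matrix is tilted to the class GC target.  The default gives the preferred
    base ~55% probability: over a 76-base window that is an overwhelming
    class signal (a small convolutional network separates the classes almost
    perfectly), while per-base entropy stays high enough that unrelated
    sequences from one source essentially never share a 24-mer — much
    sharper preferences lock sequences onto a common deterministic cycle,
    and spuriously shared words would let assembly chimerize transcripts in
    a way real unrelated genomes (24-mer collision odds ~ L^2 / 4^24) never
    show.
    """
    gc_targets = gc_targets or {"human": 0.50, "viral": 0.40, "bacterial": 0.65}
    rng = np.random.default_rng(rng_seed)
    models: dict[str, OriginModel] = {}
    for label in ORIGIN_LABELS:
        preferred = rng.integers(0, 4, size=16)
        raw = np.full((16, 4), 1.0)
        raw[np.arange(16), preferred] = np.exp(sharpness)
        raw *= rng.uniform(0.7, 1.3, size=(16, 4))  # break symmetry
        raw /= raw.sum(axis=1, keepdims=True)
        models[label] = _calibrate_gc(raw, label, gc_targets[label])
    return models


def sample_sequence(model: OriginModel, length: int, rng: np.random.Generator) -> str:
    """Draw one sequence of the given length from the Markov source."""
    if length < 2:
        raise ValueError("length must be >= 2")
    pi = model.stationary_context()
    ctx = int(rng.choice(16, p=pi))
    out = [ctx // 4, ctx % 4]
    cum = np.cumsum(model.transition, axis=1)
    u = rng.random(length - 2)
    for i in range(length - 2):
        nxt = int(np.searchsorted(cum[ctx], u[i], side="right"))
        nxt = min(nxt, 3)
        out.append(nxt)
        ctx = 4 * (ctx % 4) + nxt
    return "".join(BASES[b] for b in out)


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------

_GENUS_NAMES = [
    "Alphagenus", "Betagenus", "Gammagenus", "Deltagenus", "Epsilongenus",
    "Zetagenus", "Etagenus", "Thetagenus", "Iotagenus", "Kappagenus",
]


@dataclass
class ReferenceRecord:
    accession: str
    sequence: str
    label: str  # origin class: human / viral / bacterial
    species: str = ""
    genus: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


def make_references(
    origin_models: dict[str, OriginModel],
    n_per_class: int,
    length_range: tuple[int, int] = (500, 1500),
    rng_seed: int = 0,
    n_genera: int = 5,
) -> list[ReferenceRecord]:
    """Generate labeled reference sequences, deterministic per seed.

    Bacterial and viral records carry species/genus names (bacterial genera
    cycle through a fixed pool of ``n_genera`` names, several species each)
    so downstream annotation has taxa to assign.
    """
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    lo, hi = length_range
    if n_per_class > 0 and lo < 200:
        raise ValueError("reference lengths must be >= 200")
    rng = np.random.default_rng(rng_seed)
    prefixes = {"human": "HUM", "viral": "VIR", "bacterial": "BAC"}
    records: list[ReferenceRecord] = []
    for label in ORIGIN_LABELS:
        model = origin_models[label]
        for i in range(n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = sample_sequence(model, length, rng)
            acc = f"{prefixes[label]}_{i:04d}"
            species = genus = ""
            if label == "bacterial":
                genus = _GENUS_NAMES[i % n_genera]
                species = f"{genus} sp{i:03d}"
            elif label == "viral":
                genus = "Virusgenus"
                species = f"Synthvirus sp{i:03d}"
            records.append(ReferenceRecord(acc, seq, label, species, genus))
    return records


def references_to_fasta(records: list[ReferenceRecord]) -> str:
    """Serialize references with structured headers accession|label|species|genus."""
    buf = io.StringIO()
    for r in records:
        buf.write(f">{r.accession}|{r.label}|{r.species}|{r.genus}\n")
        for i in range(0, len(r.sequence), 80):
            buf.write(r.sequence[i : i + 80] + "\n")
    return buf.getvalue()


def references_from_fasta(text: str) -> list[ReferenceRecord]:
    records: list[ReferenceRecord] = []
    acc = label = species = genus = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if acc is not None:
                records.append(ReferenceRecord(acc, "".join(chunks), label, species, genus))
            fields = (line[1:].strip().split("|") + ["", "", ""])[:4]
            acc, label, species, genus = fields
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if acc is not None:
        records.append(ReferenceRecord(acc, "".join(chunks), label, species, genus))
    return records


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class SampleSpec:
    """One sequencing sample: what was planted and how reads were corrupted."""

    sample_id: str
    patient_id: str
    cohort: str  # case | control
    planted: list[tuple[str, float]] = field(default_factory=list)
    read_length: int = 75
    n_rate: float = 0.0
    host_read_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length not in (75, 76):
            raise ValueError("read_length must be 75 or 76")
        if not (0.0 <= self.n_rate <= 0.05):
            raise ValueError("n_rate must be in [0, 0.05]")
        if self.host_read_count < 0:
            raise ValueError("host_read_count must be >= 0")
        for acc, cov in self.planted:
            if cov < 0:
                raise ValueError(f"coverage for {acc} must be >= 0")


@dataclass
class ReadRecord:
    read_id: str
    sequence: str


def _corrupt(seq: str, n_rate: float, rng: np.random.Generator) -> str:
    if n_rate <= 0:
        return seq
    mask = rng.random(len(seq)) < n_rate
    if not mask.any():
        return seq
    chars = list(seq)
    for i in np.flatnonzero(mask):
        chars[i] = "N"
    return "".join(chars)


def make_reads(
    spec: SampleSpec, references: list[ReferenceRecord]
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate a read set plus a ground-truth table.

    Per planted transcript the read count is Poisson(coverage * L / read_len)
    with uniform start positions; host reads are drawn uniformly from the
    human-labeled references.  The truth table maps read_id to its source
    accession, position and origin label.
    """
    by_acc = {r.accession: r for r in references}
    for acc, _ in spec.planted:
        if acc not in by_acc:
            raise KeyError(f"planted accession {acc!r} not in references")
    host_refs = [r for r in references if r.label == "human"]
    if spec.host_read_count > 0 and not host_refs:
        raise KeyError("host reads requested but no human-labeled references")

    rng = np.random.default_rng(spec.rng_seed)
    reads: list[ReadRecord] = []
    truth_rows: list[tuple[str, str, int, str]] = []
    serial = 0

    def emit(ref: ReferenceRecord, pos: int) -> None:
        nonlocal serial
        raw = ref.sequence[pos : pos + spec.read_length]
        rid = f"{spec.sample_id}:{serial:06d}"
        serial += 1
        reads.append(ReadRecord(rid, _corrupt(raw, spec.n_rate, rng)))
        truth_rows.append((rid, ref.accession, pos, ref.label))

    for acc, cov in spec.planted:
        ref = by_acc[acc]
        if len(ref) < spec.read_length or cov == 0:
            continue
        n_reads = int(rng.poisson(cov * len(ref) / spec.read_length))
        positions = rng.integers(0, len(ref) - spec.read_length + 1, size=n_reads)
        for pos in positions:
            emit(ref, int(pos))

    for _ in range(spec.host_read_count):
        ref = host_refs[int(rng.integers(len(host_refs)))]
        pos = int(rng.integers(0, len(ref) - spec.read_length + 1))
        emit(ref, pos)

    truth = pd.DataFrame(truth_rows, columns=["read_id", "accession", "position", "origin"])
    return reads, truth


def reads_to_fastq(reads: list[ReadRecord]) -> str:
    """FASTQ serialization; quality is constant 'I' (never used downstream)."""
    buf = io.StringIO()
    for r in reads:
        buf.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return buf.getvalue()


def reads_from_fastq(text: str) -> list[ReadRecord]:
    lines = [ln for ln in text.splitlines() if ln]
    if len(lines) % 4:
        raise ValueError("malformed FASTQ: record count not a multiple of 4")
    return [ReadRecord(lines[i][1:].split()[0], lines[i + 1]) for i in range(0, len(lines), 4)]


# ---------------------------------------------------------------------------
# Cohorts and survival
# ---------------------------------------------------------------------------

RACE_LEVELS = ("white", "black", "asian", "other")
COVARIATES = ("race", "age", "sex", "weight", "smoking", "seq_depth")


@dataclass
class CohortSpec:
    """Cohort shape, confounding strength, and outcome-linked features.

    ``covariate_effects`` maps a covariate name to the shift applied to case
    patients: for continuous covariates (age, weight, seq_depth) the shift is
    in standard deviations of that covariate; for binary covariates (sex,
    smoking) and race it is a log-odds shift.  ``feature_hazard`` maps a
    presence-matrix feature to a log hazard ratio on survival.
    """

    n_case: int
    n_control: int
    covariate_effects: dict[str, float] = field(default_factory=dict)
    feature_hazard: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_case and n_control must be >= 1")
        if not (0.0 <= self.censoring_rate <= 1.0):
            raise ValueError("censoring_rate must be in [0, 1]")
        unknown = set(self.covariate_effects) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


# baseline covariate distributions (means, sds in natural units)
_CONTINUOUS = {"age": (55.0, 12.0), "weight": (75.0, 15.0), "seq_depth": (50e6, 15e6)}
_BINARY_BASE = {"sex": 0.5, "smoking": 0.3}
_RACE_BASE = np.array([0.6, 0.2, 0.1, 0.1])


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def make_cohort(
    spec: CohortSpec, presence: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate covariate and survival tables for a two-cohort study.

    Returns ``(covariates, survival)``.  Covariates has one row per patient
    (patient_id, cohort, race, age, sex, weight, smoking, seq_depth).
    Survival has one row per patient and endpoint in {OS, DFS}: exponential
    event times with per-patient hazard ``base * exp(sum feature_hazard *
    presence)``, censored uniformly with probability ``censoring_rate``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_case + spec.n_control
    patient_ids = [f"P{i:04d}" for i in range(n)]
    is_case = np.array([1] * spec.n_case + [0] * spec.n_control)

    if presence is not None:
        missing = set(spec.feature_hazard) - set(presence.columns)
        if missing:
            raise ValueError(f"feature_hazard features not in presence matrix: {sorted(missing)}")
        if list(presence.index) != patient_ids and len(presence) != n:
            raise ValueError("presence matrix patients do not match generated patients")
    elif spec.feature_hazard:
        raise ValueError("feature_hazard given but no presence matrix")

    eff = spec.covariate_effects
    cov = {"patient_id": patient_ids, "cohort": np.where(is_case == 1, "case", "control")}
    for name, (mu, sd) in _CONTINUOUS.items():
        z = rng.normal(size=n) + eff.get(name, 0.0) * is_case
        cov[name] = mu + sd * z
    for name, p0 in _BINARY_BASE.items():
        logit0 = np.log(p0 / (1 - p0))
        p = np.array([_sigmoid(logit0 + eff.get(name, 0.0) * c) for c in is_case])
        cov[name] = (rng.random(n) < p).astype(int)
    # race effect shifts the odds of the non-reference levels for cases
    race_levels = []
    for c in is_case:
        w = _RACE_BASE.copy()
        if c and eff.get("race", 0.0):
            w[1:] *= np.exp(eff["race"])
        w = w / w.sum()
        race_levels.append(RACE_LEVELS[int(rng.choice(4, p=w))])
    cov["race"] = race_levels
    covariates = pd.DataFrame(cov).set_index("patient_id")

    # survival: exponential with hazard tied to designated features
    loghr = np.zeros(n)
    if presence is not None and spec.feature_hazard:
        pres = presence.reindex(covariates.index) if set(presence.index) == set(patient_ids) else presence
        for feat, beta in spec.feature_hazard.items():
            loghr += beta * pres[feat].to_numpy(dtype=float)
    rows = []
    for endpoint, median_days in (("OS", 1000.0), ("DFS", 600.0)):
        base_rate = np.log(2.0) / median_days
        t = rng.exponential(1.0 / (base_rate * np.exp(loghr)))
        censored = rng.random(n) < spec.censoring_rate
        time = np.where(censored, t * rng.random(n), t)
        event = (~censored).astype(int)
        for pid, ti, ev in zip(patient_ids, time, event):
            rows.append((pid, endpoint, max(float(ti), 1e-3), int(ev)))
    survival = pd.DataFrame(rows, columns=["patient_id", "endpoint", "time", "event"])
    return covariates, survival


def confounded_null_feature(
    covariates: pd.DataFrame,
    covariate: str = "age",
    slope: float = 1.0,
    rng: np.random.Generator | int = 0,
) -> pd.Series:
    """A Bernoulli feature whose log-odds depend only on one covariate.

    Such a feature is associated with cohort membership only through the
    confounded covariate — the null case a confounder-corrected test must
    not reject.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = covariates[covariate].to_numpy(dtype=float)
    if covariate in _CONTINUOUS:
        mu, sd = _CONTINUOUS[covariate]
        x = (x - mu) / sd
    p = 1.0 / (1.0 + np.exp(-slope * x))
    return pd.Series(rng.random(len(x)) < p, index=covariates.index)
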