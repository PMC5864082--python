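"""Ground-truthed synthetic data for pooled-fitness analysis.

Emulates a pooled competition of heterozygous barcoded deletion strains:
an initial pool (P) grown through batch culture (B) and then continuous
(chemostat) culture sampled at early / mid / late steady state (ESS, MSS,
LSS), with two biological repeats per condition.  Each strain carries a
per-condition fitness effect ``s`` — a log2 growth-rate offset per
generation — so the pool composition evolves as

    f_i  <-  f_i * 2^(1 + s_i) / sum_j f_j * 2^(1 + s_j)

per generation.  Sequencing is modelled as multinomial sampling of reads
over strain abundances with independent per-base substitution errors.
Colony plates and monoculture growth curves for the haploid screen are
generated with the same ground-truth bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from barfit.catalog import (
    CONDITIONS,
    SampleRow,
    SampleSheet,
    BarcodeCatalog,
    StrainRecord,
)
from barfit.errors import ParameterError

# 3' tails of the paired-end amplification primers used for the UPTAG and
# DOWNTAG libraries; reads are laid out as  flank5 + TAG + flank3  with
# flank3 the reverse complement of the reverse-primer tail.
UPTAG_FLANK5 = "GATGTCCACGAGGTCTCT"
UPTAG_REV_PRIMER = "GTCGACCTGCAGCGTACG"
DOWNTAG_FLANK5 = "CGAGCTCGAATTCATCGAT"
DOWNTAG_REV_PRIMER = "CGGTGTCGGTCTCGTAG"

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


UPTAG_FLANK3 = revcomp(UPTAG_REV_PRIMER)
DOWNTAG_FLANK3 = revcomp(DOWNTAG_REV_PRIMER)

FLANKS = {"up": (UPTAG_FLANK5, UPTAG_FLANK3), "down": (DOWNTAG_FLANK5, DOWNTAG_FLANK3)}

#: stage-transition generation counts; MSS and LSS are measured from ESS
DEFAULT_GENERATIONS = {"P->B": 6, "B->ESS": 4, "ESS->MSS": 20, "ESS->LSS": 30}

STAGE_ORDER = ("P", "B", "ESS", "MSS", "LSS")

# rough class composition of the ncRNA deletion collection
_CLASS_PROPS = [
    ("tRNA", 0.45),
    ("SUT", 0.25),
    ("CUT", 0.15),
    ("snoRNA", 0.10),
    ("snRNA", 0.01),
    ("other", 0.04),
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic competition experiment."""

    n_strains: int = 500
    generations: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENERATIONS))
    depth: int = 100_000  # reads per sample per TAG library
    error_rate: float = 0.0  # per-base substitution probability
    fraction_null: float = 0.90
    fraction_hi: float = 0.05
    fraction_hp: float = 0.05
    effect_size: float = 0.2  # |s|, log2 growth-rate offset per generation
    rep_jitter_sd: float = 0.02  # per-repeat jitter on s
    n_bio_reps: int = 2
    tag_length: int = 20
    seed: int = 0

    def validate(self) -> None:
        fr = self.fraction_null + self.fraction_hi + self.fraction_hp
        if abs(fr - 1.0) > 1e-12:
            raise ParameterError(f"effect-model fractions sum to {fr}, not 1")
        if not (0.0 <= self.error_rate < 0.1):
            raise ParameterError(f"error_rate {self.error_rate} outside [0, 0.1)")
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.n_strains < 1:
            raise ParameterError("n_strains must be >= 1")
        if any(g < 0 for g in self.generations.values()):
            raise ParameterError("generation counts must be >= 0")
        if self.n_bio_reps < 1:
            raise ParameterError("n_bio_reps must be >= 1")


@dataclass
class PoolState:
    """Relative strain abundances at one sampled stage of one repeat."""

    stage: str
    replicate: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ParameterError("pool fractions must be >= 0 and sum to 1")
        self.fractions = f


def _spawn(seed: int, *key: object) -> np.random.Generator:
    """Deterministic named substream of the master seed."""
    h = np.uint32(2166136261)
    for part in key:
        for byte in str(part).encode():
            h = np.uint32((int(h) ^ byte) * 16777619 & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, int(h)]))


def make_catalog(n_strains: int, tag_length: int = 20, seed: int = 0) -> BarcodeCatalog:
    """Random strain/barcode catalog with unique TAGs and class labels."""
    rng = _spawn(seed, "catalog")
    tags: set[str] = set()
    bases = np.array(list("ACGT"))
    while len(tags) < 2 * n_strains:
        seq = "".join(bases[rng.integers(0, 4, size=tag_length)])
        tags.add(seq)
    ordered = sorted(tags)
    rng.shuffle(ordered)
    classes = [c for c, _ in _CLASS_PROPS]
    probs = np.array([p for _, p in _CLASS_PROPS])
    cls_draw = rng.choice(len(classes), size=n_strains, p=probs / probs.sum())
    counters = {c: 0 for c in classes}
    records = []
    for i in range(n_strains):
        cls = classes[cls_draw[i]]
        counters[cls] += 1
        prefix = {"tRNA": "tS(SIM)", "snoRNA": "SNR", "snRNA": "SNRU", "SUT": "SUT",
                  "CUT": "CUT", "other": "NCR"}[cls]
        name = f"{prefix}{9000 + counters[cls]}"
        records.append(
            StrainRecord(
                strain_id=f"S{i:04d}",
                ncrna_name=name,
                ncrna_class=cls,
                uptag=ordered[2 * i],
                downtag=ordered[2 * i + 1],
            )
        )
    return BarcodeCatalog(records=records)


def draw_truth(config: SimConfig, conditions: tuple[str, ...] = CONDITIONS,
               strain_ids: list[str] | None = None) -> pd.DataFrame:
    """Assign each strain a per-condition fitness effect and class label.

    Returns a tidy frame (strain_id, condition, s, label) with label in
    {HI, HP, null}; sign(s) matches the label by construction.
    """
    config.validate()
    if strain_ids is None:
        strain_ids = [f"S{i:04d}" for i in range(config.n_strains)]
    rows = []
    for cond in conditions:
        rng = _spawn(config.seed, "truth", cond)
        u = rng.random(len(strain_ids))
        for sid, x in zip(strain_ids, u):
            if x < config.fraction_hi:
                s, label = -config.effect_size, "HI"
            elif x < config.fraction_hi + config.fraction_hp:
                s, label = +config.effect_size, "HP"
            else:
                s, label = 0.0, "null"
            rows.append((sid, cond, s, label))
    return pd.DataFrame(rows, columns=["strain_id", "condition", "s", "label"])


def _propagate(fractions: np.ndarray, s: np.ndarray, generations: int) -> np.ndarray:
    """Closed form of the per-generation competitive update."""
    if generations == 0:
        return fractions.copy()
    w = fractions * np.exp2(generations * (1.0 + s))
    return w / w.sum()


def simulate_pool(config: SimConfig, condition: str,
                  truth: pd.DataFrame | None = None) -> tuple[list[PoolState], pd.DataFrame]:
    """Simulate pool composition at every sampled stage of one condition.

    Each biological repeat gets an independent per-strain jitter
    ``s' = s + N(0, rep_jitter_sd)`` so replicates are non-identical.
    Deterministic given ``config.seed``.
    """
    config.validate()
    if truth is None:
        truth = draw_truth(config, conditions=(condition,))
    tt = truth[truth["condition"] == condition].reset_index(drop=True)
    if len(tt) != config.n_strains:
        raise ParameterError(
            f"truth covers {len(tt)} strains, config says {config.n_strains}")
    s = tt["s"].to_numpy(dtype=float)
    gens = config.generations
    states: list[PoolState] = []
    f0 = np.full(config.n_strains, 1.0 / config.n_strains)
    for rep in range(1, config.n_bio_reps + 1):
        rng = _spawn(config.seed, "jitter", condition, rep)
        if config.rep_jitter_sd > 0:
            s_rep = s + rng.normal(0.0, config.rep_jitter_sd, size=s.shape)
        else:
            s_rep = s
        f_b = _propagate(f0, s_rep, gens["P->B"])
        f_ess = _propagate(f_b, s_rep, gens["B->ESS"])
        f_mss = _propagate(f_ess, s_rep, gens["ESS->MSS"])
        f_lss = _propagate(f_ess, s_rep, gens["ESS->LSS"])
        states += [
            PoolState("P", rep, f0),
            PoolState("B", rep, f_b),
            PoolState("ESS", rep, f_ess),
            PoolState("MSS", rep, f_mss),
            PoolState("LSS", rep, f_lss),
        ]
    return states, tt


def sample_counts(state: PoolState, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Summed UPTAG+DOWNTAG read counts for one sample (two multinomial draws)."""
    up = rng.multinomial(depth, state.fractions)
    down = rng.multinomial(depth, state.fractions)
    return up + down


def simulate_count_matrix(config: SimConfig, condition: str,
                          truth: pd.DataFrame | None = None,
                          stages: tuple[str, ...] = STAGE_ORDER,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain×sample count matrix sampled directly from pool states.

    Statistically identical to emitting error-free reads and counting them,
    without the FASTQ round trip; used for calibration studies at depths
    where full read emission is wasteful.  Columns are named
    ``{condition}_{stage}_r{rep}``.
    """
    states, tt = simulate_pool(config, condition, truth)
    cols = {}
    for st in states:
        if st.stage not in stages:
            continue
        rng = _spawn(config.seed, "counts", condition, st.stage, st.replicate)
        cols[f"{condition}_{st.stage}_r{st.replicate}"] = sample_counts(st, config.depth, rng)
    idx = tt["strain_id"].tolist()
    return pd.DataFrame(cols, index=pd.Index(idx, name="strain_id")), tt


def _mutate(seq: str, e: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < e
    if not hit.any():
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in np.nonzero(hit)[0]:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def emit_reads(state: PoolState, catalog: BarcodeCatalog, sample: SampleRow,
               config: SimConfig, rng: np.random.Generator | None = None,
               ) -> tuple[list[tuple[str, str]], list[tuple[str, str]], np.ndarray]:
    """Emit one sample's UPTAG and DOWNTAG reads.

    Returns ``(uptag_reads, downtag_reads, draws)`` where each read is a
    ``(header, sequence)`` pair (quality is constant 'I'), and ``draws`` is
    the 2×n_strains matrix of multinomial read counts actually drawn — the
    simulator's own record against which error-free counting can be checked
    exactly.  The 6-mer sample index and the true source strain are carried
    in the read header.
    """
    config.validate()
    if len(catalog) != state.fractions.size:
        raise ParameterError("catalog does not cover the simulated strains")
    if rng is None:
        rng = _spawn(config.seed, "reads", sample.sample_id)
    draws = np.vstack([
        rng.multinomial(config.depth, state.fractions),
        rng.multinomial(config.depth, state.fractions),
    ])
    out: tuple[list[tuple[str, str]], list[tuple[str, str]]] = ([], [])
    for run_i, which in enumerate(("up", "down")):
        flank5, flank3 = FLANKS[which]
        reads = out[run_i]
        serial = 0
        for rec, n in zip(catalog.records, draws[run_i]):
            tag = rec.uptag if which == "up" else rec.downtag
            template = flank5 + tag + flank3
            for _ in range(int(n)):
                serial += 1
                seq = template
                if config.error_rate > 0:
                    seq = _mutate(seq, config.error_rate, rng)
                header = (f"{sample.sample_id}.{which}.{serial} "
                          f"index={sample.index6} strain={rec.strain_id}")
                reads.append((header, seq))
    return out[0], out[1], draws


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs as 4-line FASTQ with constant quality."""
    with open(path, "wt", newline="\n") as fh:
        for header, seq in reads:
            fh.write(f"@{header}\n{seq}\n+\n{'I' * len(seq)}\n")


def make_sample_sheet(conditions: tuple[str, ...], n_bio_reps: int = 2,
                      stages: tuple[str, ...] = STAGE_ORDER) -> SampleSheet:
    """Sample sheet enumerating condition×stage×repeat with distinct 6-mers."""
    bases = "ACGT"
    rows = []
    k = 0
    for cond in conditions:
        for stage in stages:
            for rep in range(1, n_bio_reps + 1):
                idx = "".join(bases[(k // 4**p) % 4] for p in range(6))
                rows.append(SampleRow(
                    sample_id=f"{cond}_{stage}_r{rep}",
                    index6=idx, condition=cond, stage=stage, replicate=rep))
                k += 1
    return SampleSheet(rows=rows)


# ---------------------------------------------------------------------------
# colony plates and growth curves


def simulate_plates(n_strains: int, n_replicates: int = 4, grid: tuple[int, int] = (16, 24),
                    reduced_fraction: float = 0.10, reduced_mean: float = 0.6,
                    noise_sd: float = 0.05, plate_effect_sd: float = 0.10,
                    n_wt_per_plate: int = 8, seed: int = 0):
    """Arrayed colony plates with a majority normal class and a reduced class.

    Colony size = plate_scale × class_mean × lognormal(0, noise_sd), with
    plate_scale itself lognormal(0, plate_effect_sd) per plate.  Wild-type
    control colonies (class mean 1) are placed at the first
    ``n_wt_per_plate`` positions of each plate.  Returns
    ``(plates, truth)`` where plates is a list of
    :class:`barfit.screen.PlateGrid` and truth maps strains to their class.
    """
    from barfit.screen import PlateGrid

    nrow, ncol = grid
    if nrow < 2 or ncol < 2:
        raise ParameterError(f"plate grid must be at least 2x2, got {grid}")
    if not (0.0 <= reduced_fraction < 1.0):
        raise ParameterError("reduced_fraction outside [0, 1)")
    rng = _spawn(seed, "plates")
    per_plate = nrow * ncol - n_wt_per_plate
    if per_plate <= 0:
        raise ParameterError("no positions left for strains after wild-type controls")

    n_reduced = int(round(reduced_fraction * n_strains))
    labels = np.array(["reduced"] * n_reduced + ["normal"] * (n_strains - n_reduced))
    rng.shuffle(labels)
    strain_ids = [f"S{i:04d}" for i in range(n_strains)]
    truth = pd.DataFrame({"strain_id": strain_ids, "label": labels})
    mean_of = {sid: (reduced_mean if lab == "reduced" else 1.0)
               for sid, lab in zip(strain_ids, labels)}

    # replicate positions for every strain, shuffled across plates
    slots = np.repeat(np.arange(n_strains), n_replicates)
    rng.shuffle(slots)
    n_plates = int(np.ceil(slots.size / per_plate))
    plates = []
    cursor = 0
    for p in range(n_plates):
        scale = float(np.exp(rng.normal(0.0, plate_effect_sd))) if plate_effect_sd > 0 else 1.0
        sizes = np.full((nrow, ncol), np.nan)
        names = np.full((nrow, ncol), "", dtype=object)
        wt_positions = []
        flat = [(r, c) for r in range(nrow) for c in range(ncol)]
        for k, (r, c) in enumerate(flat):
            if k < n_wt_per_plate:
                mean, name = 1.0, "WT"
                wt_positions.append((r, c))
            elif cursor < slots.size:
                sid = strain_ids[slots[cursor]]
                mean, name = mean_of[sid], sid
                cursor += 1
            else:
                continue
            noise = float(np.exp(rng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            sizes[r, c] = scale * mean * noise
            names[r, c] = name
        plates.append(PlateGrid(plate_id=f"plate{p + 1:02d}", sizes=sizes,
                                strain_ids=names, wt_positions=wt_positions))
    return plates, truth


def simulate_growth_curve(times: np.ndarray, K: float = 1.0, r: float = 1.0,
                          t_mid: float = 5.0, noise_sd: float = 0.0, seed: int = 0):
    """Logistic OD trajectory OD(t) = K / (1 + exp(-r (t - t_mid))) + noise."""
    from barfit.screen import GrowthCurve

    times = np.asarray(times, dtype=float)
    od = K / (1.0 + np.exp(-r * (times - t_mid)))
    if noise_sd > 0:
        od = od + _spawn(seed, "growth").normal(0.0, noise_sd, size=od.shape)
    return GrowthCurve(times=times, od=od)
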