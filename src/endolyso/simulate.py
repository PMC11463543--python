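"""Synthetic organelle-IP data with known ground truth.

Emulates a tagged-vs-untagged immunoprecipitation proteomics study on
induced neurons: multiplexed reporter-intensity matrices with
compartment-structured enrichment effects, annotation tables, a
differentiation time-course, and protein sequences carrying planted
recycling-motif instances.  Every generator is driven by named substreams
of a single seed, so adding a generator never perturbs the others, and
every dataset is emitted together with a :class:`SimTruth` record of the
planted effects so downstream sensitivity/specificity can be measured
against complete truth.

The measurement model for the IP experiment is deliberately simple — a
per-protein baseline plus an additive enrichment effect for tagged
channels plus log-normal noise.  Reporter-ion ratio compression and
isotopic impurity are not modelled; a single log2-scale Gaussian noise
term is enough to exercise the downstream statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, DesignTable, IntensityMatrix, ProteinSequence

COMPARTMENTS = ("lysosome", "endosome", "plasma_membrane",
                "mitochondrion", "ER", "Golgi", "cytosol")

#: hydrophobic residue set used for motif planting (matches the scanner's)
PHI_RESIDUES = "AVLIMFWY"


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible child RNG of ``seed``.

    The stream key is a CRC32 of the name, so generators draw from
    independent streams and a new named generator never shifts the draws
    of existing ones.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), zlib.crc32(name.encode()))))


# ---------------------------------------------------------------------------
# Configuration and truth records
# ---------------------------------------------------------------------------

_DEFAULT_FRACTIONS: dict[str, float] = {
    "lysosome": 0.12,
    "endosome": 0.10,
    "plasma_membrane": 0.20,
    "mitochondrion": 0.12,
    "ER": 0.12,
    "Golgi": 0.09,
    "cytosol": 0.25,
}


@dataclass
class SimConfig:
    """Parameters of a simulated organelle-IP experiment.

    ``enrichment_effect`` is the mean log2 shift of true target-compartment
    proteins in their own IP (default 2.5, comfortably above a 1.0 log2 FC
    call threshold); ``core_effect`` is the weaker cross-capture shift of
    shared endolysosomal core proteins in the *other* IP (default 1.5).
    ``pm_cargo_rate`` is the fraction of plasma-membrane proteins that are
    endocytic cargo, i.e. additionally enriched in the endosome IP.
    ``noise_sd`` is the log2-scale measurement noise (default 0.35).
    """

    n_proteins: int = 500
    compartment_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS))
    enrichment_effect: float = 2.5
    core_effect: float = 1.5
    core_fraction: float = 0.2
    pm_cargo_rate: float = 0.3
    noise_sd: float = 0.35
    replicates: int = 3
    missing_rate: float = 0.0
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    cell_state: str = "iNeuron"
    ip_types: tuple[str, ...] = ("endo", "lyso")
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.compartment_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        unknown = set(self.compartment_fractions) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments {sorted(unknown)}")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if self.replicates < 2:
            raise ValueError("replicates < 2: two-group statistics undefined")


@dataclass
class MotifRecord:
    """One true motif occurrence (planted or accidental) in a sequence."""

    protein: str
    motif_type: str  # "SNX27" | "SNX17"
    start: int       # 1-based inclusive
    end: int
    peptide: str
    planted: bool


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic dataset.

    ``proteins`` holds one row per protein: compartment, true log2
    enrichment in each IP, transmembrane-segment count, cell-membrane flag,
    and the endolysosomal-core / endocytic-cargo class flags.  ``motifs``
    lists every true motif occurrence in any emitted sequence, planted or
    accidental, so scanner sensitivity and specificity are computable
    against complete truth.
    """

    proteins: pd.DataFrame
    motifs: list[MotifRecord] = field(default_factory=list)
    seed: int = 0
    config: SimConfig | None = None

    def to_file(self, path) -> None:
        out = self.proteins.copy()
        out.index.name = "protein"
        out.to_csv(path, sep="\t")

    def planted_motifs(self) -> list[MotifRecord]:
        return [m for m in self.motifs if m.planted]


# ---------------------------------------------------------------------------
# IP experiment
# ---------------------------------------------------------------------------

def _make_design(cfg: SimConfig) -> DesignTable:
    rows = []
    for ip in cfg.ip_types:
        for cond in ("tagged", "control"):
            for r in range(1, cfg.replicates + 1):
                rows.append({
                    "channel": f"{ip}_{cond}_{r}",
                    "condition": cond,
                    "ip_type": ip,
                    "cell_state": cfg.cell_state,
                    "replicate": r,
                })
    return DesignTable(pd.DataFrame(rows))


def simulate_ip_experiment(cfg: SimConfig, noise_seed: int | None = None
                           ) -> tuple[IntensityMatrix, DesignTable, SimTruth]:
    """Simulate a tagged-vs-control IP reporter-intensity matrix.

    The log2 intensity of protein *i* in channel *c* is

        baseline_i + effect_i(ip, condition) + eps,   eps ~ N(0, noise_sd)

    with baseline_i ~ N(baseline_mean, baseline_sd).  ``effect_i`` equals
    ``enrichment_effect`` in tagged channels of the protein's own IP
    (endosome proteins and cargo-class plasma-membrane proteins in the
    endo IP; lysosomal proteins in the lyso IP), ``core_effect`` in tagged
    channels of the other IP for shared endolysosomal-core proteins, and 0
    otherwise.  Values are returned on the raw intensity scale (2**x) and
    masked missing at ``missing_rate``.

    Protein-level truth (compartments, effects, baselines) and measurement
    noise come from separate named substreams, so passing a different
    ``noise_seed`` (default: the config seed) re-measures the *same*
    underlying experiment — the way to simulate independent replicate
    datasets of one biological truth.
    """
    design = _make_design(cfg)
    rng = substream(cfg.seed, "ip_truth")
    rng_noise = substream(cfg.seed if noise_seed is None else noise_seed, "ip_noise")

    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(n)]
    comps = list(cfg.compartment_fractions)
    probs = np.array([cfg.compartment_fractions[c] for c in comps], dtype=float)
    compartment = rng.choice(comps, size=n, p=probs / probs.sum())

    is_lyso = compartment == "lysosome"
    is_endo = compartment == "endosome"
    is_pm = compartment == "plasma_membrane"
    core = (is_lyso | is_endo) & (rng.random(n) < cfg.core_fraction)
    cargo = is_pm & (rng.random(n) < cfg.pm_cargo_rate)

    endo_fc = np.where(is_endo | cargo, cfg.enrichment_effect,
                       np.where(core & is_lyso, cfg.core_effect, 0.0))
    lyso_fc = np.where(is_lyso, cfg.enrichment_effect,
                       np.where(core & is_endo, cfg.core_effect, 0.0))

    tm = rng.integers(0, 13, size=n)
    tm = np.where(is_pm, np.maximum(tm, 1), tm)
    cell_membrane = is_pm

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)

    cols = {}
    for _, ch in design.frame.iterrows():
        effect = np.zeros(n)
        if ch["condition"] == "tagged":
            effect = endo_fc if ch["ip_type"] == "endo" else lyso_fc
        log2_val = baseline + effect + rng_noise.normal(0.0, cfg.noise_sd, size=n)
        cols[ch["channel"]] = np.exp2(log2_val)
    values = pd.DataFrame(cols, index=proteins)

    if cfg.missing_rate > 0:
        mask = rng_noise.random(values.shape) < cfg.missing_rate
        values = values.mask(mask)

    truth_frame = pd.DataFrame({
        "compartment": compartment,
        "true_lfc_endo": endo_fc,
        "true_lfc_lyso": lyso_fc,
        "tm_count": tm,
        "cell_membrane": cell_membrane,
        "endolysosomal_core": core,
        "endocytic_cargo": cargo,
    }, index=proteins)
    truth = SimTruth(proteins=truth_frame, seed=cfg.seed, config=cfg)
    return IntensityMatrix(values=values, design=design), design, truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_DOMAINS = ("Ig-like C2-type", "Fibronectin type-III", "EGF-like",
            "Protein kinase", "Cadherin", "LDL-receptor class A")
_FAMILIES = ("Nectin", "LDLR", "Neurexin", "Immunoglobulin",
             "Tyrosine protein kinase", "Tetraspanin")


def simulate_annotations(truth: SimTruth,
                         synaptic_odds: float = 4.0,
                         base_set_rate: float = 0.15,
                         n_random_sets: int = 3,
                         domain_rate: float = 0.5,
                         family_rate: float = 0.5,
                         seed: int | None = None) -> pd.DataFrame:
    """Annotation table for the proteins of a simulated experiment.

    Compartment labels, TM counts and the cell-membrane flag are copied
    from truth (cell-membrane proteins are guaranteed at least one TM
    segment by construction).  A "synaptic" gene set emulating a curated
    synaptic ontology is assigned with odds multiplied by
    ``synaptic_odds`` among plasma-membrane proteins (odds 1 gives a null
    set for calibration tests); additional random sets are assigned at the
    base rate.  Domain/family labels are drawn for cargo-eligible proteins
    so the presence-matrix classifier has non-trivial input.

    Returns a DataFrame indexed by protein with columns ``compartments``
    (frozenset), ``tm_count``, ``cell_membrane``, ``gene_sets``,
    ``domains``, ``families``.
    """
    rng = substream(truth.seed if seed is None else seed, "annotations")
    t = truth.proteins
    n = len(t)
    is_pm = t["cell_membrane"].to_numpy(dtype=bool)

    p0 = base_set_rate
    odds = synaptic_odds * p0 / (1 - p0)
    p_pm = odds / (1 + odds)
    p_syn = np.where(is_pm, p_pm, p0)
    in_syn = rng.random(n) < p_syn

    set_members: dict[str, np.ndarray] = {"synaptic": in_syn}
    for j in range(n_random_sets):
        set_members[f"set{j + 1}"] = rng.random(n) < p0

    domains = [frozenset() for _ in range(n)]
    families = [frozenset() for _ in range(n)]
    eligible = is_pm & (t["tm_count"].to_numpy() >= 1)
    for i in np.flatnonzero(eligible):
        if rng.random() < domain_rate:
            domains[i] = frozenset({_DOMAINS[rng.integers(len(_DOMAINS))]})
        if rng.random() < family_rate:
            families[i] = frozenset({_FAMILIES[rng.integers(len(_FAMILIES))]})

    gene_sets = [
        frozenset(name for name, flags in set_members.items() if flags[i])
        for i in range(n)
    ]
    return pd.DataFrame({
        "compartments": [frozenset({c}) for c in t["compartment"]],
        "tm_count": t["tm_count"].to_numpy(),
        "cell_membrane": is_pm,
        "gene_sets": gene_sets,
        "domains": domains,
        "families": families,
    }, index=t.index)


# ---------------------------------------------------------------------------
# Sequences with planted sorting motifs
# ---------------------------------------------------------------------------

def _scan_truth_motifs(seqs: Sequence[ProteinSequence],
                       planted: set[tuple[str, str, int]]) -> list[MotifRecord]:
    # Post-hoc exhaustive scan so accidental background matches enter truth.
    from .motifs import scan_snx17, scan_snx27
    records: list[MotifRecord] = []
    for s in seqs:
        hit = scan_snx27(s)
        if hit is not None:
            records.append(MotifRecord(s.id, "SNX27", hit.start, hit.end, hit.matched,
                                       planted=(s.id, "SNX27", hit.start) in planted))
        for hit in scan_snx17(s):
            records.append(MotifRecord(s.id, "SNX17", hit.start, hit.end, hit.matched,
                                       planted=(s.id, "SNX17", hit.start) in planted))
    return records


def simulate_sequences(n: int,
                       plant_snx27: float = 0.3,
                       plant_snx17: float = 0.3,
                       length_range: tuple[int, int] = (40, 100),
                       seed: int = 0) -> tuple[list[ProteinSequence], list[MotifRecord]]:
    """Random protein sequences with sorting motifs planted at known sites.

    Background residues are i.i.d. uniform over the 20-letter alphabet, so
    the background match probability of each motif grammar is closed-form.
    With probability ``plant_snx27`` the final three residues are
    overwritten with an [S/T]-x-Phi PDZ-binding motif; with probability
    ``plant_snx17`` a Phi-x-N-x-x-[Y/F] FERM-binding motif is written at a
    random internal position at least 10 residues from either terminus.
    The returned motif records include accidental background matches
    (``planted=False``), found by exhaustive post-hoc scan.
    """
    lo, hi = length_range
    if lo < 16:
        raise ValueError("length_range lower bound < 16: peptide windows undefined")
    if not (0 <= plant_snx27 <= 1 and 0 <= plant_snx17 <= 1):
        raise ValueError("plant probabilities must be in [0, 1]")
    rng = substream(seed, "sequences")
    aa = np.array(list(AMINO_ACIDS))
    phi = np.array(list(PHI_RESIDUES))

    seqs: list[ProteinSequence] = []
    planted: set[tuple[str, str, int]] = set()
    for i in range(n):
        pid = f"S{i:05d}"
        L = int(rng.integers(lo, hi + 1))
        chars = rng.choice(aa, size=L)
        if rng.random() < plant_snx17 and L >= 26:
            # start0 in [10, L-16] keeps the 6-mer >= 10 residues from both ends
            start0 = int(rng.integers(10, L - 15))
            motif = [rng.choice(phi), rng.choice(aa), "N",
                     rng.choice(aa), rng.choice(aa), rng.choice(np.array(["Y", "F"]))]
            chars[start0:start0 + 6] = motif
            planted.add((pid, "SNX17", start0 + 1))
        if rng.random() < plant_snx27:
            chars[L - 3:] = [rng.choice(np.array(["S", "T"])), rng.choice(aa), rng.choice(phi)]
            planted.add((pid, "SNX27", L - 2))
        seqs.append(ProteinSequence(id=pid, seq="".join(chars)))

    return seqs, _scan_truth_motifs(seqs, planted)


# ---------------------------------------------------------------------------
# Differentiation time-course
# ---------------------------------------------------------------------------

def _shape_up(t: np.ndarray) -> np.ndarray:
    return t


def _shape_down(t: np.ndarray) -> np.ndarray:
    return 1.0 - t


def _shape_transient(t: np.ndarray) -> np.ndarray:
    return np.exp(-((t - 0.5) / 0.22) ** 2)


DEFAULT_SHAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "monotone_up": _shape_up,
    "monotone_down": _shape_down,
    "transient": _shape_transient,
}

#: default sampling days across the 12-day neuronal differentiation
DEFAULT_DAYS = (0, 2, 4, 6, 8, 10, 12)


def simulate_timecourse(n_proteins: int = 300,
                        days: Sequence[float] = DEFAULT_DAYS,
                        shapes: Mapping[str, Callable] | None = None,
                        noise_sd: float = 0.2,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Abundance trajectories across differentiation with true cluster labels.

    Each protein is assigned one of the template shapes (evaluated on
    normalized time over ``days``, unit amplitude) plus Gaussian noise of
    standard deviation ``noise_sd`` in amplitude units.  Returns the
    profile matrix (proteins x days) and the true shape label per protein.
    """
    shapes = dict(DEFAULT_SHAPES) if shapes is None else dict(shapes)
    if len(shapes) < 2:
        raise ValueError("need at least 2 cluster shapes")
    rng = substream(seed, "timecourse")
    days_arr = np.asarray(days, dtype=float)
    t = (days_arr - days_arr.min()) / (days_arr.max() - days_arr.min())

    names = sorted(shapes)
    labels = [names[int(rng.integers(len(names)))] for _ in range(n_proteins)]
    rows = np.stack([
        shapes[lab](t) + rng.normal(0.0, noise_sd, size=len(t))
        for lab in labels
    ])
    idx = [f"P{i:05d}" for i in range(n_proteins)]
    profile = pd.DataFrame(rows, index=idx, columns=[f"day{int(d)}" for d in days_arr])
    return profile, pd.Series(labels, index=idx, name="true_cluster")
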