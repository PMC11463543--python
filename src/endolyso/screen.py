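"""Complex-prediction screening of motif peptides and sequence logos.

Peptide queries are scored by an interface-confidence (ipTM) predictor —
either an ingested table of externally computed scores or the built-in
mock used with synthetic truth — and pass the screen only with a score
strictly above the cutoff (default 0.6).  A protein passes at the
protein level if any of its motif windows passes.  Top/bottom subsets by
score feed position-frequency-matrix logos whose per-position information
content is log2(20) minus the Shannon entropy of the residue
distribution.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS
from .motifs import PeptideQuery
from .simulate import MotifRecord

log = logging.getLogger("endolyso")

GAP = "-"


# ---------------------------------------------------------------------------
# Predictors
# ---------------------------------------------------------------------------

def read_score_table(path) -> dict[tuple[str, str, str], float]:
    """Ingest externally computed ipTM scores.

    The TSV needs columns ``protein``, ``motif_type``, ``peptide``,
    ``iptm``; keys match :meth:`PeptideQuery.key`.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"protein", "motif_type", "peptide", "iptm"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: score table missing columns {sorted(missing)}")
    return {
        (str(r.protein), str(r.motif_type), str(r.peptide)): float(r.iptm)
        for r in df.itertuples()
    }


def table_predictor(scores: dict[tuple[str, str, str], float]) -> Callable:
    """Predictor backed by an ingested score table (missing -> NaN)."""
    def predict(q: PeptideQuery) -> float:
        if q.key() not in scores:
            log.warning("[screen] no score for %s/%s; excluded from counts",
                        q.protein, q.motif_type)
            return float("nan")
        return scores[q.key()]
    return predict


def _query_rng(q: PeptideQuery, seed: int) -> np.random.Generator:
    # stable per-(query, seed) stream: same query always scores the same
    digest = hashlib.sha256(
        f"{q.protein}|{q.motif_type}|{q.peptide}|{seed}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "big"))


def mock_predictor(truth_motifs: Iterable[MotifRecord], seed: int = 0,
                   mu_planted: float = 0.8, mu_background: float = 0.3,
                   noise_sd: float = 0.1) -> Callable:
    """Truth-informed mock ipTM scorer (test double for a real predictor).

    A query whose window contains a planted motif of its type scores
    clamp01(mu_planted + N(0, noise_sd)); anything else scores around
    mu_background.  Scores are deterministic per (query, seed) via a
    hashed substream.
    """
    planted: set[tuple[str, str, int, int]] = {
        (m.protein, m.motif_type, m.start, m.end)
        for m in truth_motifs if m.planted
    }

    def is_planted(q: PeptideQuery) -> bool:
        lo, hi = q.window
        return any(p == q.protein and t == q.motif_type and lo <= s and e <= hi
                   for (p, t, s, e) in planted)

    def predict(q: PeptideQuery) -> float:
        mu = mu_planted if is_planted(q) else mu_background
        eps = _query_rng(q, seed).normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        return float(np.clip(mu + eps, 0.0, 1.0))

    return predict


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenResult:
    """One scored peptide query with its pass/fail call."""

    query: PeptideQuery
    iptm: float
    passed: bool


@dataclass
class ScreenReport:
    """All screen results plus protein-level and role-level tallies."""

    results: list[ScreenResult]
    iptm_cutoff: float

    @property
    def scored(self) -> list[ScreenResult]:
        return [r for r in self.results if np.isfinite(r.iptm)]

    def role_counts(self, role: str) -> tuple[int, int]:
        """(passing, total) motif-level counts for one role."""
        rs = [r for r in self.scored if r.query.role == role]
        return sum(r.passed for r in rs), len(rs)

    def per_protein(self) -> pd.DataFrame:
        """Best score per (protein, motif_type); a protein passes if any
        of its windows passes."""
        rows: dict[tuple[str, str], dict] = {}
        for r in self.scored:
            key = (r.query.protein, r.query.motif_type)
            cur = rows.get(key)
            if cur is None or r.iptm > cur["best_iptm"]:
                rows[key] = {"protein": key[0], "motif_type": key[1],
                             "role": r.query.role, "best_iptm": r.iptm,
                             "passed": r.passed}
            elif r.passed:
                rows[key]["passed"] = True
        return (pd.DataFrame(rows.values(),
                             columns=["protein", "motif_type", "role",
                                      "best_iptm", "passed"])
                .sort_values(["motif_type", "protein"], kind="stable")
                .reset_index(drop=True))

    def summary(self) -> str:
        per = self.per_protein()
        lines = [f"ipTM screen (cutoff > {self.iptm_cutoff})"]
        for mt in sorted(per["motif_type"].unique()):
            sub = per[per["motif_type"] == mt]
            for role in sorted(sub["role"].unique()):
                rr = sub[sub["role"] == role]
                k, n = self.role_counts_for(mt, role)
                lines.append(
                    f"  {mt} {role}: {int(rr['passed'].sum())}/{len(rr)} proteins pass "
                    f"({k}/{n} motif windows)")
        return "\n".join(lines)

    def role_counts_for(self, motif_type: str, role: str) -> tuple[int, int]:
        rs = [r for r in self.scored
              if r.query.role == role and r.query.motif_type == motif_type]
        return sum(r.passed for r in rs), len(rs)


def run_screen(queries: Sequence[PeptideQuery], predictor: Callable,
               iptm_cutoff: float = 0.6) -> ScreenReport:
    """Score every query; pass requires iptm strictly above the cutoff."""
    results = []
    for q in queries:
        score = float(predictor(q))
        passed = bool(np.isfinite(score) and score > iptm_cutoff)
        results.append(ScreenResult(query=q, iptm=score, passed=passed))
    return ScreenReport(results=results, iptm_cutoff=iptm_cutoff)


# ---------------------------------------------------------------------------
# Logos
# ---------------------------------------------------------------------------

@dataclass
class PositionFrequencyMatrix:
    """Per-position residue probabilities and information content (bits)."""

    probs: pd.DataFrame  # positions x 20 residues
    information: np.ndarray
    n_sequences: int
    pseudocount: float

    def __post_init__(self) -> None:
        sums = self.probs.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("position probabilities must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        out = self.probs.copy()
        out["information_bits"] = self.information
        return out


def align_right(peptides: Sequence[str], width: int | None = None) -> list[str]:
    """Right-align C-terminal peptides, left-padding short ones with gaps."""
    width = width or max(len(p) for p in peptides)
    return [GAP * (width - len(p)) + p for p in peptides]


def build_logo(peptides: Sequence[str], pseudocount: float = 0.5) -> PositionFrequencyMatrix:
    """Position frequency matrix with information content per position.

    All peptides must have equal length after alignment (pad C-terminal
    sets with :func:`align_right` first); gap characters are excluded
    from the counts.  IC_j = log2(20) - H_j where H_j is the Shannon
    entropy of the position's residue distribution (uniform background).
    """
    if not peptides:
        raise ValueError("no peptides")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"unequal peptide lengths after alignment: {sorted(lengths)}")
    width = lengths.pop()
    counts = np.zeros((width, len(AMINO_ACIDS)))
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for p in peptides:
        for i, r in enumerate(p.upper()):
            if r in col:
                counts[i, col[r]] += 1
            elif r != GAP and r != "X":
                raise ValueError(f"invalid residue {r!r} in peptide {p!r}")
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a position has no observed residues and zero pseudocount")
    probs = counts / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=1)
    ic = np.log2(len(AMINO_ACIDS)) - h
    return PositionFrequencyMatrix(
        probs=pd.DataFrame(probs, columns=list(AMINO_ACIDS),
                           index=pd.RangeIndex(1, width + 1, name="position")),
        information=ic, n_sequences=len(peptides), pseudocount=pseudocount)


def select_top_bottom(report: ScreenReport, n_top: int, n_bottom: int,
                      motif_type: str | None = None
                      ) -> tuple[list[ScreenResult], list[ScreenResult]]:
    """Top-N and bottom-N scored results by ipTM, ties broken by protein id."""
    rs = [r for r in report.scored
          if motif_type is None or r.query.motif_type == motif_type]
    by_desc = sorted(rs, key=lambda r: (-r.iptm, r.query.protein))
    by_asc = sorted(rs, key=lambda r: (r.iptm, r.query.protein))
    return by_desc[:n_top], by_asc[:n_bottom]
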