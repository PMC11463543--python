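"""Compartment annotation joins, set overlaps, and gene-set enrichment.

Annotation tables are DataFrames indexed by protein with columns
``compartments`` (frozenset of labels), ``tm_count`` (int), ``cell_membrane``
(bool), ``gene_sets``, ``domains``, ``families`` (frozensets).  Proteins
carrying several compartment labels contribute to every label — there is
no "primary location" arbitration, matching the multi-colour volcano
annotation convention.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .io import GeneSetCollection

log = logging.getLogger("endolyso")

ANNOTATION_SET_COLUMNS = ("compartments", "gene_sets", "domains", "families")


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV (set-valued columns are ';'-joined)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ANNOTATION_SET_COLUMNS:
        if col in df.columns:
            df[col] = [
                frozenset(str(v).split(";")) if isinstance(v, str) and v else frozenset()
                for v in df[col].fillna("")
            ]
    df["cell_membrane"] = df["cell_membrane"].astype(bool)
    df["tm_count"] = df["tm_count"].astype(int)
    return df


def write_annotation_table(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    for col in ANNOTATION_SET_COLUMNS:
        if col in out.columns:
            out[col] = [";".join(sorted(v)) for v in out[col]]
    out.index.name = "protein"
    out.to_csv(path, sep="\t")


def compartment_summary(enrichment: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Distribution of log2FC per compartment label (count, mean, quartiles).

    The input is a per-protein enrichment table and an annotation table;
    multi-compartment proteins contribute to every one of their labels.
    Quartiles use the conventional linear-interpolation definition.
    """
    shared = enrichment.index.intersection(ann.index)
    rows = []
    labels = sorted(set().union(*ann.loc[shared, "compartments"])) if len(shared) else []
    for label in labels:
        members = [p for p in shared if label in ann.at[p, "compartments"]]
        vals = enrichment.loc[members, "log2FC"].dropna().to_numpy()
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({
            "compartment": label,
            "count": len(vals),
            "mean_log2FC": float(np.mean(vals)),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
        })
    return pd.DataFrame(rows, columns=["compartment", "count", "mean_log2FC",
                                       "q1", "median", "q3"])


def overlap_sets(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Disjoint-region counts and memberships for 2-3 named sets.

    Each row is one region of the Venn diagram, keyed by which sets its
    members belong to; region counts always sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError(f"overlap report supports 2-3 sets, got {len(sets)}")
    names = list(sets)
    rows = []
    for r in range(len(names), 0, -1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(*(set(sets[n]) for n in names if n not in combo))
            region = inside - outside
            rows.append({
                "region": "&".join(combo),
                "n_sets": r,
                "count": len(region),
                "members": ";".join(sorted(region)),
            })
    return pd.DataFrame(rows)


def classify_state_selectivity(selective: set[str],
                               abundance_ratio: dict[str, float],
                               tau: float = 1.0) -> dict:
    """Classify state-selective proteins by relative abundance between states.

    ``abundance_ratio`` maps protein to the log2 ratio of its abundance in
    the reference state over the other state.  A protein is "higher" when
    the ratio is >= tau, "lower" when <= -tau, otherwise "equal"; proteins
    without a ratio fall into an "unquantified" bin.  Proportions are
    reported over the quantified proteins and sum to 1.
    """
    if not selective:
        raise ValueError("empty selective set")
    quantified = {p for p in selective if p in abundance_ratio
                  and np.isfinite(abundance_ratio[p])}
    coverage = len(quantified) / len(selective)
    if coverage < 0.8:
        raise ValueError(f"abundance ratios cover only {coverage:.0%} of the "
                         "selective set (need >= 80%)")
    counts = {"higher": 0, "equal": 0, "lower": 0}
    for p in quantified:
        r = abundance_ratio[p]
        if r >= tau:
            counts["higher"] += 1
        elif r <= -tau:
            counts["lower"] += 1
        else:
            counts["equal"] += 1
    n = len(quantified)
    return {
        "counts": counts,
        "proportions": {k: v / n for k, v in counts.items()},
        "n_quantified": n,
        "n_unquantified": len(selective) - n,
        "tau": tau,
    }


def geneset_enrichment(fg: set[str], universe: set[str],
                       collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set.

    For a foreground of n proteins drawn from a universe of N, a set with
    K members in the universe and k in the foreground gets
    p = P[X >= k], X ~ Hypergeom(N, K, n), BH-adjusted across sets.
    The universe should be the quantified proteins of the stratum, not the
    whole proteome, to avoid detection-bias inflation.
    """
    stray = set(fg) - set(universe)
    if stray:
        raise ValueError(f"foreground not contained in universe: {sorted(stray)[:10]}")
    N, n = len(universe), len(fg)
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & set(universe)
        K = len(members)
        k = len(members & set(fg))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out
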