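"""Differential enrichment of tagged organelle IPs versus untagged controls.

The model is a moderated two-group comparison in log2 space.  For each
protein *g* with n_t tagged and n_c control observations, the pooled
residual variance s2_g (d_g = n_t + n_c - 2 df) is shrunk toward a prior
variance s0^2 with prior degrees of freedom d0, estimated empirically
across proteins by moment-matching log(s2_g) against its scaled-F
sampling distribution.  The moderated statistic

    t_g = log2FC_g / sqrt(s2_post_g * (1/n_t + 1/n_c)),
    s2_post_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

is referred to a t distribution with d0 + d_g degrees of freedom (a
normal when d0 is infinite).  Two-sided p-values are adjusted across
proteins by Benjamini-Hochberg, and a protein is called enriched when
log2FC >= lfc_cutoff and q <= q_cutoff.  Strata (ip_type x cell_state)
are analysed independently, with no cross-stratum variance sharing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import DesignTable, IntensityMatrix, RunConfig

log = logging.getLogger("endolyso")

#: sentinel degrees of freedom treated as infinite
D0_MAX = 1e12


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_log2(m: IntensityMatrix, scope: str = "condition") -> IntensityMatrix:
    """Log2-transform and median-center channels, removing loading offsets.

    Each channel's median (over its finite values) is shifted to the grand
    median of channel medians.  With ``scope="condition"`` (default) the
    grand median is taken within each (ip_type, cell_state, condition)
    group, so per-channel loading and labelling-efficiency offsets are
    removed while the tagged-vs-control contrast is preserved exactly —
    global centering would shrink planted effects whenever the enriched
    minority shifts a tagged channel's median.  ``scope="global"`` centers
    every channel to the one grand median.  Missing values stay missing.
    """
    if m.log2:
        raise ValueError("matrix is already on the log2 scale")
    if scope not in ("condition", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    vals = np.log2(m.values.where(m.values > 0))
    n_finite = vals.notna().sum(axis=0)
    if (n_finite == 0).any():
        bad = n_finite.index[n_finite == 0].tolist()
        raise ValueError(f"all-missing channel(s): {bad}")
    low = n_finite.index[n_finite < 10].tolist()
    if low:
        log.warning("[enrich] channel(s) with < 10 finite values: %s", low)
    medians = vals.median(axis=0)
    if scope == "global":
        centered = vals - (medians - medians.median())
    else:
        design = m.design.frame.set_index("channel")
        centered = vals.copy()
        groups = design.groupby(["ip_type", "cell_state", "condition"]).groups
        for _, channels in groups.items():
            chans = [c for c in channels]
            grand = medians[chans].median()
            centered[chans] = vals[chans] - (medians[chans] - grand)
    return IntensityMatrix(values=centered, design=m.design, log2=True)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance prior
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EBayesModel:
    """Variance prior (d0, s0^2) shared across proteins of one stratum."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0 (np.inf allowed)")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")

    @property
    def infinite(self) -> bool:
        return not np.isfinite(self.d0) or self.d0 >= D0_MAX


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _group_stats(vals: pd.DataFrame, tagged: list[str], control: list[str]):
    """Per-protein group means, pooled variance and df (vectorised)."""
    t = vals[tagged].to_numpy(dtype=float)
    c = vals[control].to_numpy(dtype=float)
    ok_t, ok_c = np.isfinite(t), np.isfinite(c)
    n_t = ok_t.sum(axis=1)
    n_c = ok_c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = np.where(ok_t, t, 0.0).sum(axis=1) / np.where(n_t > 0, n_t, np.nan)
        mean_c = np.where(ok_c, c, 0.0).sum(axis=1) / np.where(n_c > 0, n_c, np.nan)
        ss_t = np.where(ok_t, (t - mean_t[:, None]) ** 2, 0.0).sum(axis=1)
        ss_c = np.where(ok_c, (c - mean_c[:, None]) ** 2, 0.0).sum(axis=1)
    d_g = np.maximum(n_t - 1, 0) + np.maximum(n_c - 1, 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = np.where(d_g > 0, (ss_t + ss_c) / np.where(d_g > 0, d_g, 1), np.nan)
    return mean_t, mean_c, n_t, n_c, s2, d_g


def fit_ebayes(m: IntensityMatrix, design: DesignTable | None = None,
               stratum: tuple[str, str] | None = None) -> EBayesModel:
    """Estimate the variance prior (d0, s0^2) for one stratum.

    Per-protein pooled variances s2_g with d_g residual df are matched in
    moments to the scaled-F sampling distribution of s2 under the prior:
    writing z_g = log s2_g and e_g = z_g - psi(d_g/2) + log(d_g/2),

        E[e_g]   = log s0^2 - psi(d0/2) + log(d0/2)
        Var[e_g] = psi'(d_g/2) + psi'(d0/2)

    so d0 comes from inverting the trigamma function on the excess
    variance of e_g and s0^2 from the corrected mean.  If the observed
    variance of e_g does not exceed its sampling component, the prior is
    degenerate (d0 = inf, all proteins share s0^2).  With fewer than 20
    usable proteins the fit falls back to d0 = inf with s0^2 the median
    observed variance.
    """
    if not m.log2:
        raise ValueError("fit_ebayes expects a log2-scale matrix (normalize first)")
    design = design or m.design
    if stratum is None:
        strata = design.strata()
        if len(strata) != 1:
            raise ValueError(f"matrix has strata {strata}; pass `stratum=`")
        stratum = strata[0]
    tagged, control = design.stratum_channels(*stratum)
    *_, s2, d_g = _group_stats(m.values, tagged, control)

    ok = (d_g > 0) & np.isfinite(s2) & (s2 > 0)
    s2_ok, d_ok = s2[ok], d_g[ok].astype(float)
    if ok.sum() < 20:
        s0 = float(np.median(s2_ok)) if len(s2_ok) else 1.0
        log.warning("[enrich] only %d usable proteins; falling back to d0=inf, "
                    "s0_sq=median(s2)=%.4g", int(ok.sum()), s0)
        return EBayesModel(d0=np.inf, s0_sq=s0)
    return fit_variance_prior(s2_ok, d_ok)


def fit_variance_prior(s2: np.ndarray, d_g: np.ndarray) -> EBayesModel:
    """Moment-match (d0, s0^2) from per-protein variances and their df."""
    s2 = np.asarray(s2, dtype=float)
    d_g = np.asarray(d_g, dtype=float)
    z = np.log(s2)
    if np.ptp(z) < 1e-12:
        # literally no spread: the observed variances are the prior itself
        return EBayesModel(d0=np.inf, s0_sq=float(np.mean(s2)))
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    mean_e = float(np.mean(e))
    var_e = float(np.var(e, ddof=1))
    excess = var_e - float(np.mean(special.polygamma(1, d_g / 2.0)))
    if excess <= 0:
        return EBayesModel(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    d0 = 2.0 * _trigamma_inverse(excess)
    if d0 >= D0_MAX:
        return EBayesModel(d0=np.inf, s0_sq=float(np.exp(mean_e)))
    s0_sq = float(np.exp(mean_e + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesModel(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Missing p-values propagate as missing and do not count toward the
    number of tests.  Ties are handled by the stable sort.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    pv = p[ok]
    n = pv.size
    if n == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(n)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q


# ---------------------------------------------------------------------------
# Moderated test
# ---------------------------------------------------------------------------

def test_enrichment(m: IntensityMatrix, design: DesignTable | None,
                    model: EBayesModel, cfg: RunConfig,
                    stratum: tuple[str, str] | None = None) -> pd.DataFrame:
    """Per-protein moderated enrichment test for one stratum.

    Returns a DataFrame indexed by protein with columns ``log2FC``, ``s2``,
    ``t_mod``, ``p``, ``q``, ``enriched``, ``n_tagged``, ``n_control``.
    Proteins with fewer than two finite values in either group are
    reported with missing statistics and ``enriched=False``.
    """
    if not m.log2:
        raise ValueError("test_enrichment expects a log2-scale matrix")
    design = design or m.design
    if stratum is None:
        strata = design.strata()
        if len(strata) != 1:
            raise ValueError(f"matrix has strata {strata}; pass `stratum=`")
        stratum = strata[0]
    tagged, control = design.stratum_channels(*stratum)
    if not tagged or not control:
        raise ValueError(f"empty stratum {stratum}")
    mean_t, mean_c, n_t, n_c, s2, d_g = _group_stats(m.values, tagged, control)

    testable = (n_t >= 2) & (n_c >= 2)
    lfc = np.where(testable, mean_t - mean_c, np.nan)

    d0, s0 = model.d0, model.s0_sq
    with np.errstate(invalid="ignore", divide="ignore"):
        if model.infinite:
            s2_post = np.full_like(s2, s0)
            df = np.full_like(s2, np.inf)
        else:
            s2_post = (d0 * s0 + d_g * s2) / (d0 + d_g)
            df = d0 + d_g
        se = np.sqrt(s2_post * (1.0 / n_t + 1.0 / n_c))
        t_mod = np.where(testable, lfc / se, np.nan)
    p = np.where(np.isfinite(t_mod), 2.0 * stats.t.sf(np.abs(t_mod), df), np.nan)
    q = bh_adjust(p)
    enriched = np.isfinite(q) & np.isfinite(lfc) \
        & (lfc >= cfg.lfc_cutoff) & (q <= cfg.q_cutoff)

    return pd.DataFrame({
        "log2FC": lfc,
        "s2": np.where(d_g > 0, s2, np.nan),
        "t_mod": t_mod,
        "p": p,
        "q": q,
        "enriched": enriched,
        "n_tagged": n_t,
        "n_control": n_c,
    }, index=m.values.index)


# ---------------------------------------------------------------------------
# Replicate-dataset reproducibility
# ---------------------------------------------------------------------------

def compare_replicate_datasets(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Reproducibility report for two independent enrichment tables.

    Returns the Jaccard index of the enriched sets, the Pearson r of
    log2FC over shared tested proteins, and overlap counts.
    """
    if a.empty or b.empty:
        raise ValueError("both enrichment tables must be non-empty")
    shared = a.index.intersection(b.index)
    ea = set(a.index[a["enriched"].fillna(False)])
    eb = set(b.index[b["enriched"].fillna(False)])
    union = ea | eb
    jaccard = len(ea & eb) / len(union) if union else 0.0
    report = {
        "n_shared": int(len(shared)),
        "n_enriched_a": len(ea),
        "n_enriched_b": len(eb),
        "n_enriched_both": len(ea & eb),
        "jaccard": jaccard,
        "pearson_r": np.nan,
    }
    if len(shared) == 0:
        log.warning("[enrich] no shared proteins between datasets")
        return report
    x = a.loc[shared, "log2FC"].to_numpy(dtype=float)
    y = b.loc[shared, "log2FC"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
        report["pearson_r"] = float(stats.pearsonr(x[ok], y[ok]).statistic)
    else:
        log.warning("[enrich] log2FC correlation undefined (too few shared values)")
    return report


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class EnrichmentModel:
    """Moderated two-group enrichment model for one IP stratum.

    Parameters
    ----------
    matrix : IntensityMatrix
        Raw (or already log2-normalized) reporter intensities.
    design : DesignTable, optional
        Defaults to the matrix's own design.
    stratum : (ip_type, cell_state), optional
        Required when the design contains several strata.

    Examples
    --------
    >>> model = EnrichmentModel(matrix, stratum=("endo", "iNeuron"))
    >>> res = model.fit(lfc_cutoff=1.0, q_cutoff=0.01)
    >>> res.n_enriched
    """

    def __init__(self, matrix: IntensityMatrix, design: DesignTable | None = None,
                 stratum: tuple[str, str] | None = None):
        self.design = design or matrix.design
        if stratum is None:
            strata = self.design.strata()
            if len(strata) != 1:
                raise ValueError(f"design has strata {strata}; pass `stratum=`")
            stratum = strata[0]
        self.stratum = stratum
        self.matrix = matrix if matrix.log2 else normalize_log2(matrix)

    @classmethod
    def from_dataframe(cls, intensities: pd.DataFrame, design: pd.DataFrame,
                       **kw) -> "EnrichmentModel":
        dt = DesignTable(design)
        return cls(IntensityMatrix(values=intensities, design=dt), dt, **kw)

    def fit(self, lfc_cutoff: float = 1.0, q_cutoff: float = 0.01,
            config: RunConfig | None = None) -> "EnrichmentResults":
        cfg = config or RunConfig(lfc_cutoff=lfc_cutoff, q_cutoff=q_cutoff)
        prior = fit_ebayes(self.matrix, self.design, self.stratum)
        table = test_enrichment(self.matrix, self.design, prior, cfg, self.stratum)
        return EnrichmentResults(self, prior, cfg, table)


class EnrichmentResults:
    """Fit results: per-protein enrichment table, prior, and call counts."""

    def __init__(self, model: EnrichmentModel, prior: EBayesModel,
                 config: RunConfig, table: pd.DataFrame):
        self.model = model
        self.prior = prior
        self.config = config
        self.table = table

    @property
    def enriched(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["enriched"]])

    @property
    def n_enriched(self) -> int:
        return int(self.table["enriched"].sum())

    @property
    def n_tested(self) -> int:
        return int(self.table["p"].notna().sum())

    def summary(self) -> str:
        ip, state = self.model.stratum
        d0 = "inf" if self.prior.infinite else f"{self.prior.d0:.2f}"
        lines = [
            "Moderated organelle-IP enrichment",
            "=" * 46,
            f"stratum:           {ip}-IP, {state}",
            f"proteins:          {len(self.table)} ({self.n_tested} tested)",
            f"prior df (d0):     {d0}",
            f"prior var (s0^2):  {self.prior.s0_sq:.4f}",
            f"call thresholds:   log2FC >= {self.config.lfc_cutoff}, "
            f"q <= {self.config.q_cutoff}",
            f"enriched:          {self.n_enriched}",
        ]
        return "\n".join(lines)

    def to_file(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "protein", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")
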