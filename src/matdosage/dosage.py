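"""Differential transcript-dosage statistics.

The core is an empirical-Bayes moderated two-sample t-statistic on log2
expression: per-gene pooled sample variances s2 (d residual df) are
shrunk toward a prior variance s0_sq with prior df d0, both estimated by
moment matching on z = log(s2),

    z = log(s2) follows (up to a constant) log chi^2_d scaled by the
    true variance, so  var(z) = trigamma(d/2) + trigamma(d0/2)  and the
    mean of z identifies s0_sq.

The moderated statistic  t = log2FC / sqrt(s2_post * (1/nA + 1/nB))
with s2_post = (d0*s0_sq + d*s2) / (d0 + d) is referred to a t
distribution with d0 + d degrees of freedom (standard Normal when d0 is
infinite). False-discovery control is Benjamini-Hochberg, implemented as
the step-up rule. Relative qPCR quantification follows the 2^-ddCt
scheme with Ct values normalized against the mean of the reference
genes and a reference condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "EBayesPrior",
    "estimate_ebayes_prior",
    "moderated_t",
    "adjust_bh",
    "call_deregulated",
    "ddct_fold_change",
]


@dataclass
class EBayesPrior:
    d0: float  # prior degrees of freedom, may be math.inf
    s0_sq: float  # prior variance on the log2 scale

    def validate(self) -> None:
        if not self.d0 > 0:
            raise ValueError("prior degrees of freedom must be > 0")
        if math.isfinite(self.d0) and not self.s0_sq > 0:
            raise ValueError("prior variance must be > 0 for finite d0")


def _trigamma_inverse(x: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires a positive argument")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_ebayes_prior(s2: np.ndarray, d: float) -> EBayesPrior:
    """Moment-matching estimate of the variance prior from per-gene s2.

    Genes with s2 == 0 carry no information about the variance
    distribution's shape and are ignored (with a warning); if all are
    zero the input is degenerate.
    """
    s2 = np.asarray(s2, dtype=float)
    if d < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("degenerate variance input: all per-gene s2 are zero")
    if positive.size < s2.size:
        warnings.warn(
            f"{s2.size - positive.size} genes with zero variance ignored "
            "in prior estimation",
            stacklevel=2,
        )
    if positive.size < 2:
        raise ValueError("need >= 2 genes with positive s2 to estimate the prior")

    z = np.log(positive)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    resid = evar - float(special.polygamma(1, d / 2.0))
    if resid <= 0:
        # log-variances under-dispersed relative to pure chi^2 sampling:
        # one common variance explains everything, estimated by the mean s2
        prior = EBayesPrior(d0=math.inf, s0_sq=float(np.mean(positive)))
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        s0_sq = math.exp(emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
        prior = EBayesPrior(d0=d0, s0_sq=s0_sq)
    prior.validate()
    return prior


def _group_stats(matrix: pd.DataFrame, label: str) -> tuple[pd.Series, pd.Series, int]:
    n = matrix.shape[1]
    if n < 2:
        raise ValueError(f"group {label!r} has {n} replicate(s); need >= 2")
    return matrix.mean(axis=1), matrix.var(axis=1, ddof=1), n


def moderated_t(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    prior: EBayesPrior | None = None,
) -> pd.DataFrame:
    """Moderated-t comparison of two log2 expression groups (B vs A).

    Returns a per-gene table with columns mean_log2_A, mean_log2_B,
    log2FC (= B - A), s2, d, s2_post, t_mod, p and BH-adjusted q.
    """
    if not matrix_a.index.equals(matrix_b.index):
        raise ValueError("group matrices must share the same gene index")
    mean_a, var_a, n_a = _group_stats(matrix_a, "A")
    mean_b, var_b, n_b = _group_stats(matrix_b, "B")
    d = n_a + n_b - 2
    s2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / d
    s2_arr = s2.to_numpy()

    if prior is None:
        if np.all(s2_arr <= 0):
            warnings.warn(
                "all per-gene variances are zero; using a degenerate prior",
                stacklevel=2,
            )
            prior = EBayesPrior(d0=math.inf, s0_sq=0.0)
        else:
            prior = estimate_ebayes_prior(s2_arr, d)

    if math.isinf(prior.d0):
        s2_post = np.full_like(s2_arr, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + d * s2_arr) / (prior.d0 + d)
        df_total = prior.d0 + d

    log2fc = (mean_b - mean_a).to_numpy()
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(log2fc == 0.0, 0.0, log2fc / se)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)

    out = pd.DataFrame(
        {
            "mean_log2_A": mean_a,
            "mean_log2_B": mean_b,
            "log2FC": log2fc,
            "s2": s2,
            "d": d,
            "s2_post": s2_post,
            "t_mod": t,
            "p": p,
            "q": adjust_bh(p),
        },
        index=matrix_a.index,
    )
    out.attrs["prior_d0"] = prior.d0
    out.attrs["prior_s0_sq"] = prior.s0_sq
    out.attrs["n_A"] = n_a
    out.attrs["n_B"] = n_b
    return out


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_i = min_{j: p_(j) >= p_(i)} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_deregulated(
    comparison: pd.DataFrame,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    use_adjusted: bool = False,
    p_comparison: str = "strict",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tri-state up/down/unchanged call from fold change and significance.

    ``up``: log2FC >= log2(fc_min) and the p-criterion holds (p < p_max
    when strict, p <= p_max when inclusive); ``down`` symmetric;
    ``unchanged`` otherwise.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (a linear-scale fold change)")
    if p_comparison not in ("strict", "inclusive"):
        raise ValueError("p_comparison must be 'strict' or 'inclusive'")
    pcol = "q" if use_adjusted else "p"
    pvals = comparison[pcol].to_numpy()
    sig = pvals < p_max if p_comparison == "strict" else pvals <= p_max
    thr = math.log2(fc_min)
    fc = comparison["log2FC"].to_numpy()
    call = np.where(
        sig & (fc >= thr), "up", np.where(sig & (fc <= -thr), "down", "unchanged")
    )
    table = comparison.copy()
    table["call"] = call
    counts = {
        "n_up": int((call == "up").sum()),
        "n_down": int((call == "down").sum()),
        "n_unchanged": int((call == "unchanged").sum()),
    }
    return table, counts


def ddct_fold_change(
    measurements: pd.DataFrame,
    reference_condition: str,
    target_gene: str,
    reference_genes: list[str],
) -> pd.DataFrame:
    """Per-sample 2^-ddCt relative quantification.

    ``measurements`` is long-format with columns sample_id, condition,
    gene, ct. Per sample: dCt = Ct(target) - mean(Ct of reference
    genes); ddCt = dCt - mean(dCt over reference-condition samples);
    fold = 2^-ddCt.
    """
    required = {"sample_id", "condition", "gene", "ct"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements must have columns {sorted(required)}")
    if not reference_genes:
        raise ValueError("need at least one reference gene")
    ct = measurements[np.isfinite(measurements["ct"]) & (measurements["ct"] > 0)]
    if len(ct) < len(measurements):
        raise ValueError("all Ct values must be finite and > 0")

    rows = []
    for sample_id, grp in measurements.groupby("sample_id", sort=False):
        by_gene = grp.set_index("gene")["ct"]
        missing = [g for g in [target_gene, *reference_genes] if g not in by_gene.index]
        if missing:
            raise ValueError(f"sample {sample_id!r} is missing Ct for {missing}")
        dct = by_gene[target_gene] - by_gene[reference_genes].mean()
        rows.append(
            {
                "sample_id": sample_id,
                "condition": grp["condition"].iloc[0],
                "delta_ct": float(dct),
            }
        )
    table = pd.DataFrame(rows)
    ref = table.loc[table["condition"] == reference_condition, "delta_ct"]
    if ref.empty:
        raise ValueError(f"no samples with reference condition {reference_condition!r}")
    table["delta_delta_ct"] = table["delta_ct"] - ref.mean()
    table["fold_change"] = 2.0 ** (-table["delta_delta_ct"])
    return table
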