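"""Differential expression calling from a normalized log2 matrix.

One exposure condition = one (injected activity, time-after-injection)
group contrasted against the mock-treated controls.  Technical replicates
are averaged into their biological replicate first; the per-probe test is
a two-sided Welch t on log2 intensities, the multiplicity correction is
Benjamini-Hochberg within the condition's filtered probe set, and a probe
is called significant when adjusted p < 0.01 and |fold change| >= 1.5
(signed convention: ratios below 1 are reported as negative reciprocals,
so |FC| >= 1 always).

With 2-3 biological replicates per group a per-probe variance estimate
has so few degrees of freedom that no probe can clear a stringent FDR
cutoff, however large its effect.  The default test therefore moderates
per-probe variances with an empirical-Bayes shrinkage toward a common
prior fitted across all probes (the standard small-n microarray
approach), which adds the prior degrees of freedom to each probe's test.
A plain Welch t (:func:`probe_test`) remains available via
``call_de(..., method="welch")``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import math

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample_id", "activity_kbq", "time_h", "bio_rep", "tech_rep", "is_control"]

Condition = tuple[float, float]  # (activity_kbq, time_h)


class DesignError(ValueError):
    """Raised for inconsistent matrix/metadata combinations."""


@dataclass
class ExpressionStudy:
    """A normalized log2 expression matrix plus its sample sheet.

    Parameters
    ----------
    matrix
        probes x samples DataFrame of log2 intensities; columns are
        sample ids.
    samples
        One row per sample with columns ``sample_id, activity_kbq,
        time_h, bio_rep, tech_rep, is_control``.
    probe_gene
        Optional probe id -> gene symbol mapping (several probe variants
        may map to one gene).
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    probe_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        miss = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if miss:
            raise DesignError(f"sample sheet lacks columns {miss}")
        self.samples = self.samples.reset_index(drop=True)
        ids = list(self.samples["sample_id"])
        if set(self.matrix.columns) != set(ids):
            raise DesignError("matrix columns and sample sheet ids disagree")
        self.matrix = self.matrix[ids]
        if not self.samples["is_control"].any():
            raise DesignError("study has no control samples")
        # a biological replicate is identified by (condition, bio_rep); its
        # technical replicates therefore share activity/time by construction,
        # but duplicate tech-rep ids within one biological replicate are a
        # sheet error
        dup = self.samples.duplicated(
            ["is_control", "activity_kbq", "time_h", "bio_rep", "tech_rep"]
        )
        if dup.any():
            raise DesignError(
                "duplicate technical replicate annotation for samples "
                f"{list(self.samples.loc[dup, 'sample_id'])}"
            )

    def conditions(self) -> list[Condition]:
        """Treated (activity, time) pairs present in the sample sheet."""
        treated = self.samples[~self.samples["is_control"].astype(bool)]
        pairs = treated[["activity_kbq", "time_h"]].drop_duplicates()
        return sorted((float(a), float(t)) for a, t in pairs.itertuples(index=False))


@dataclass(frozen=True)
class DECall:
    """Per-probe differential expression call for one condition."""

    probe: str
    condition: Condition
    fold_change: float
    p_raw: float
    p_adj: float
    significant: bool


def collapse_technical(study: ExpressionStudy) -> ExpressionStudy:
    """Average technical replicates into one column per biological replicate.

    Arithmetic mean on the log2 scale.  The collapsed sample sheet keeps
    one row per biological replicate with ``tech_rep`` set to 0; a sample
    whose (condition, bio_rep) key is unique passes through unchanged, so
    the operation is idempotent.
    """
    s = study.samples
    keys = ["is_control", "activity_kbq", "time_h", "bio_rep"]
    rows, cols = [], {}
    for key, grp in s.groupby(keys, sort=True):
        isc, act, t, b = key
        new_id = f"ctrl_b{b}" if isc else f"a{act:g}_t{t:g}_b{b}"
        cols[new_id] = study.matrix[list(grp["sample_id"])].mean(axis=1)
        rows.append(
            {
                "sample_id": new_id,
                "activity_kbq": act,
                "time_h": t,
                "bio_rep": b,
                "tech_rep": 0,
                "is_control": bool(isc),
            }
        )
    return ExpressionStudy(
        matrix=pd.DataFrame(cols, index=study.matrix.index),
        samples=pd.DataFrame(rows),
        probe_gene=study.probe_gene,
    )


def fold_change(treated_log2: np.ndarray, control_log2: np.ndarray) -> float:
    """Signed fold change between group means on the log2 scale.

    ``r = 2**(mean(treated) - mean(control))``; returned as ``r`` when
    r >= 1 and as ``-1/r`` otherwise, so upregulation is positive,
    downregulation negative and |FC| >= 1 by construction.
    """
    treated_log2 = np.asarray(treated_log2, dtype=float)
    control_log2 = np.asarray(control_log2, dtype=float)
    if treated_log2.size == 0 or control_log2.size == 0:
        raise DesignError("fold change needs non-empty groups")
    r = 2.0 ** (treated_log2.mean() - control_log2.mean())
    return float(r) if r >= 1.0 else float(-1.0 / r)


def probe_test(treated_log2: np.ndarray, control_log2: np.ndarray) -> float:
    """Two-sided Welch t-test p-value on log2 values.

    Groups of identical constant values give p = 1 (zero statistic).
    Requires >= 2 values per group for a finite statistic; smaller groups
    raise, callers exclude such probes with a logged warning.
    """
    treated_log2 = np.asarray(treated_log2, dtype=float)
    control_log2 = np.asarray(control_log2, dtype=float)
    if treated_log2.size < 2 or control_log2.size < 2:
        raise DesignError("Welch test needs >=2 values per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(treated_log2, control_log2, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if np.isclose(treated_log2.mean(), control_log2.mean()) else 0.0
    return p


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse needs a positive target")
    x = 0.5 + 1.0 / y
    for _ in range(100):
        f = float(special.polygamma(1, x)) - y
        fp = float(special.polygamma(2, x))
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * max(1.0, x):
            return x_new
        x = x_new
    return x


def fit_variance_prior(s2: np.ndarray, df_resid: float) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior of per-probe variances.

    Given residual variances ``s2`` each on ``df_resid`` degrees of
    freedom, returns ``(d0, s0_sq)``: the prior degrees of freedom and
    prior variance such that posterior variances
    ``(d0*s0_sq + df*s2) / (d0 + df)`` gain ``d0`` extra df.  Method of
    moments on log variances; ``d0 = inf`` when the observed spread of
    log variances is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df_resid / 2.0) + math.log(df_resid / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df_resid / 2.0))
    if excess <= 0:
        return math.inf, math.exp(e_mean)
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0_sq


def moderated_test(treated: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorized moderated two-group t-test over probes (rows).

    Pooled per-probe residual variances are shrunk toward an
    empirical-Bayes prior fitted across probes; the t statistic uses the
    posterior variance and gains the prior degrees of freedom.  Returns
    two-sided p-values, one per probe.
    """
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    n1, n2 = treated.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise DesignError("moderated test needs >=2 values per group")
    df_resid = n1 + n2 - 2
    ss = treated.var(axis=1, ddof=1) * (n1 - 1) + control.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df_resid
    d0, s0_sq = fit_variance_prior(s2, df_resid)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    tstat = (treated.mean(axis=1) - control.mean(axis=1)) / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    return np.minimum(p, 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, q(i) = p(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_probes(matrix: pd.DataFrame, floor_quantile: float = 0.2) -> pd.Index:
    """Detection filter: probes whose mean log2 clears an expression floor.

    The floor is the ``floor_quantile`` quantile of all matrix values
    (default 20th percentile); the surviving probe set is both the test
    set and the enrichment universe downstream.
    """
    floor = float(np.quantile(matrix.to_numpy(), floor_quantile))
    keep = matrix.mean(axis=1) >= floor
    return matrix.index[keep]


def call_de(
    study: ExpressionStudy,
    condition: Condition,
    fc_threshold: float = 1.5,
    alpha: float = 0.01,
    floor_quantile: float = 0.2,
    method: str = "moderated",
) -> pd.DataFrame:
    """Call significantly regulated probes for one exposure condition.

    Technical replicates are collapsed, probes are filtered with the
    expression floor, each surviving probe gets a p-value (moderated t
    by default, ``method="welch"`` for the plain Welch t) and a signed
    fold change against controls, p-values are BH-adjusted within the
    condition, and ``significant`` marks p_adj < alpha together with
    |FC| >= fc_threshold.

    Returns a DataFrame indexed by probe with columns ``fold_change``,
    ``p_raw``, ``p_adj``, ``significant`` (with a ``condition`` value in
    ``DataFrame.attrs``); use :func:`de_summary` for up/down counts.
    """
    cond = (float(condition[0]), float(condition[1]))
    if cond not in study.conditions():
        raise DesignError(
            f"condition {cond} not in study; available: {study.conditions()}"
        )
    collapsed = collapse_technical(study)
    s = collapsed.samples
    is_ctrl = s["is_control"].astype(bool)
    treated_ids = s.loc[
        (~is_ctrl) & (s["activity_kbq"] == cond[0]) & (s["time_h"] == cond[1]),
        "sample_id",
    ]
    control_ids = s.loc[is_ctrl, "sample_id"]
    if len(treated_ids) < 2 or len(control_ids) < 2:
        raise DesignError("need >=2 biological replicates per group for the Welch test")
    if len(treated_ids) == 2:
        log.warning(
            "condition %s has only 2 biological replicates: the per-probe "
            "test is low-power", cond
        )
    probes = filter_probes(study.matrix, floor_quantile)
    treated = collapsed.matrix.loc[probes, treated_ids].to_numpy()
    control = collapsed.matrix.loc[probes, control_ids].to_numpy()

    if method == "moderated":
        p_raw = moderated_test(treated, control)
    elif method == "welch":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(treated, control, axis=1, equal_var=False)
        p_raw = np.asarray(res.pvalue, dtype=float)
        flat = np.isnan(p_raw)
        if flat.any():  # zero variance in both groups
            same = np.isclose(treated[flat].mean(axis=1), control[flat].mean(axis=1))
            p_raw[flat] = np.where(same, 1.0, 0.0)
    else:
        raise ValueError(f"unknown test method {method!r}")

    diff = treated.mean(axis=1) - control.mean(axis=1)
    ratio = 2.0 ** diff
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)

    p_adj = benjamini_hochberg(p_raw)
    out = pd.DataFrame(
        {
            "fold_change": fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": (p_adj < alpha) & (np.abs(fc) >= fc_threshold),
        },
        index=pd.Index(probes, name="probe"),
    )
    out.attrs["condition"] = cond
    return out


def de_summary(calls: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) among significant calls, partitioned by FC sign."""
    sig = calls[calls["significant"]]
    return int((sig["fold_change"] > 0).sum()), int((sig["fold_change"] < 0).sum())


def call_all_conditions(
    study: ExpressionStudy,
    fc_threshold: float = 1.5,
    alpha: float = 0.01,
    floor_quantile: float = 0.2,
    method: str = "moderated",
) -> dict[Condition, pd.DataFrame]:
    """Run :func:`call_de` for every treated condition in the study."""
    return {
        cond: call_de(study, cond, fc_threshold, alpha, floor_quantile, method)
        for cond in study.conditions()
    }
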