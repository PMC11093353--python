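"""Hypoxia survival testing and ChIP-qPCR quantification.

Development/survival assays score each embryo as hatched/un-hatched (24 h)
and adult/non-adult (72 h) under normoxia vs hypoxia, with three biological
replicates.  Per genotype and endpoint the treatment effect is tested by a
binomial GLM with logit link and additive replicate + treatment factors
(likelihood-ratio test on the treatment term).  When that model is
inappropriate — complete separation (an arm at 0% or 100% across all
replicates) or non-convergence — a replicate-stratified randomization test
replaces it: treatment labels are permuted within each replicate and the
statistic is the difference in pooled success proportions.

ChIP-qPCR enrichment uses the efficiency-corrected comparative
quantification: the target amplicon's IP signal is normalized to input and
then to a reference amplicon,

    enrichment = E_t ** (Ct_t,input - Ct_t,IP) / E_r ** (Ct_r,input - Ct_r,IP).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DataError

__all__ = ["QpcrRecord", "SurvivalTestResult", "survival_test", "qpcr_enrichment"]

ENDPOINTS = ("hatched", "adult")

# exact enumeration is used when the stratified permutation space is this small
_EXACT_LIMIT = 250_000


@dataclass(frozen=True)
class SurvivalTestResult:
    p: float
    method: str  # "glm" | "randomization"
    statistic: float  # treatment LR chi2, or difference of pooled proportions
    proportions: dict  # treatment -> pooled success proportion


@dataclass(frozen=True)
class QpcrRecord:
    """Ct values and amplification efficiencies for one target/reference pair.

    Efficiencies are fold-amplification per cycle (2.0 = perfect doubling).
    """

    target: str
    reference: str
    eff_target: float
    eff_reference: float
    ct_target_ip: float
    ct_target_input: float
    ct_reference_ip: float
    ct_reference_input: float

    def __post_init__(self) -> None:
        for name in ("eff_target", "eff_reference"):
            e = getattr(self, name)
            if not 1.0 < e <= 2.2:
                raise DataError(f"{name} must be in (1, 2.2], got {e}")
        for name in (
            "ct_target_ip",
            "ct_target_input",
            "ct_reference_ip",
            "ct_reference_input",
        ):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")


def _validate_counts(counts: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    if endpoint not in ENDPOINTS:
        raise DataError(f"endpoint must be one of {ENDPOINTS}")
    need = {"treatment", "replicate", "n_total", f"n_{endpoint}"}
    if not need.issubset(counts.columns):
        raise DataError(f"counts table needs columns {sorted(need)}")
    df = counts[["treatment", "replicate", "n_total", f"n_{endpoint}"]].copy()
    df.columns = ["treatment", "replicate", "n", "k"]
    if ((df["k"] < 0) | (df["k"] > df["n"])).any():
        raise DataError("successes must satisfy 0 <= k <= n")
    if df["treatment"].nunique() < 2:
        raise DataError("both treatment arms are required")
    return df


def survival_test(
    counts: pd.DataFrame,
    endpoint: str = "hatched",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> SurvivalTestResult:
    """Test the treatment effect on a binary developmental endpoint.

    ``counts`` holds one genotype: columns ``treatment`` (two arms),
    ``replicate``, ``n_total`` and ``n_hatched``/``n_adult``.  Returns the
    p-value, the method actually used and the pooled per-arm proportions.
    """
    df = _validate_counts(counts, endpoint)
    arms = sorted(df["treatment"].unique())
    pooled = {
        t: df.loc[df["treatment"] == t, "k"].sum()
        / df.loc[df["treatment"] == t, "n"].sum()
        for t in arms
    }
    separated = any(p in (0.0, 1.0) for p in pooled.values())
    if not separated:
        try:
            return _glm_test(df, pooled)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            pass
        except Exception:  # pragma: no cover - defensive convergence guard
            pass
    return _randomization_test(df, pooled, n_perm=n_perm, seed=seed)


def _glm_test(df: pd.DataFrame, pooled: dict) -> SurvivalTestResult:
    endog = df[["k"]].assign(fail=df["n"] - df["k"]).to_numpy(dtype=float)
    design = pd.get_dummies(
        df[["replicate", "treatment"]].astype(str), drop_first=True, dtype=float
    )
    x_full = sm.add_constant(design, has_constant="add")
    treat_cols = [c for c in design.columns if c.startswith("treatment_")]
    x_red = x_full.drop(columns=treat_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit()
        red = sm.GLM(endog, x_red, family=sm.families.Binomial()).fit()
    if not (np.isfinite(full.llf) and np.isfinite(red.llf)):
        raise np.linalg.LinAlgError("GLM log-likelihood not finite")
    lr = 2.0 * (full.llf - red.llf)
    dof = len(treat_cols)
    p = float(stats.chi2.sf(max(lr, 0.0), dof))
    return SurvivalTestResult(p=p, method="glm", statistic=float(lr), proportions=pooled)


def _proportion_diff(k_a, n_a, k_b, n_b) -> float:
    return k_a / n_a - k_b / n_b


def _randomization_test(
    df: pd.DataFrame, pooled: dict, n_perm: int, seed: int | None
) -> SurvivalTestResult:
    """Stratified permutation of treatment labels within replicate.

    Exact when the product of per-replicate success-split ranges is small
    (the null distribution is a product of hypergeometrics); Monte Carlo
    with p = (1 + #{|T*| >= |T|}) / (1 + n_perm) otherwise.
    """
    arms = sorted(df["treatment"].unique())
    if len(arms) != 2:
        raise DataError("the randomization test supports exactly two arms")
    a, b = arms
    strata = []
    for _, rep in df.groupby("replicate"):
        ka = int(rep.loc[rep["treatment"] == a, "k"].sum())
        na = int(rep.loc[rep["treatment"] == a, "n"].sum())
        kb = int(rep.loc[rep["treatment"] == b, "k"].sum())
        nb = int(rep.loc[rep["treatment"] == b, "n"].sum())
        strata.append((ka + kb, na, nb))
    n_a_tot = sum(na for _, na, _ in strata)
    n_b_tot = sum(nb for _, _, nb in strata)
    k_a_obs = int(df.loc[df["treatment"] == a, "k"].sum())
    k_b_obs = int(df.loc[df["treatment"] == b, "k"].sum())
    t_obs = _proportion_diff(k_a_obs, n_a_tot, k_b_obs, n_b_tot)

    ranges = [
        range(max(0, s - nb), min(s, na) + 1) for s, na, nb in strata
    ]
    n_combos = int(np.prod([len(r) for r in ranges]))
    if n_combos <= _EXACT_LIMIT:
        p = 0.0
        for combo in itertools.product(*ranges):
            w = 1.0
            for ka, (s, na, nb) in zip(combo, strata):
                w *= stats.hypergeom.pmf(ka, na + nb, s, na)
            k_a = sum(combo)
            k_b = sum(s for s, _, _ in strata) - k_a
            t = _proportion_diff(k_a, n_a_tot, k_b, n_b_tot)
            if abs(t) >= abs(t_obs) - 1e-12:
                p += w
        p = min(1.0, p)
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            k_a = sum(
                rng.hypergeometric(na, nb, s) if s > 0 else 0
                for s, na, nb in strata
            )
            k_b = sum(s for s, _, _ in strata) - k_a
            t = _proportion_diff(k_a, n_a_tot, k_b, n_b_tot)
            if abs(t) >= abs(t_obs) - 1e-12:
                hits += 1
        p = (1.0 + hits) / (1.0 + n_perm)
    return SurvivalTestResult(
        p=float(p), method="randomization", statistic=float(t_obs), proportions=pooled
    )


def qpcr_enrichment(record: QpcrRecord) -> float:
    """Relative enrichment by efficiency-corrected comparative quantification.

    The target's input-normalized signal E_t**(dCt_t) is divided by the
    reference's E_r**(dCt_r), with dCt = Ct_input - Ct_IP.
    """
    d_t = record.ct_target_input - record.ct_target_ip
    d_r = record.ct_reference_input - record.ct_reference_ip
    return float(record.eff_target**d_t / record.eff_reference**d_r)
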