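"""Factorial differential-expression analysis for a randomized complete block design.

The study design is a balanced two-way layout: every treatment (genotype or
genotype+hypoxia arm) appears exactly once in each biological-replicate block.
Per gene, an additive fixed-effects ANOVA model

    y_{jb} = mu + tau_j + beta_b + e_{jb},   e ~ N(0, sigma^2)

is fitted on log2 expression values, and zero-sum linear contrasts of
treatment means are tested with the general F-test on 1 and (b-1)(t-1)
degrees of freedom.  With 3 blocks and 8 treatments the residual df is 14.

Multiplicity is handled by Storey-Tibshirani q-values.  Fold changes are
reported in the signed convention (a linear ratio r is printed as r when
r >= 1 and as -1/r otherwise, so magnitudes are always >= 1), and HIF-1
dependence is judged on the interaction contrast: the N2 hypoxia effect minus
the hif-1 mutant hypoxia effect, whose back-transform is the relative
induction N2/hif-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

__all__ = [
    "Thresholds",
    "ContrastSpec",
    "ExpressionStudy",
    "fit_contrast",
    "estimate_pi0",
    "qvalues",
    "signed_fc",
    "signed_to_linear",
    "signed_ratio",
    "classify",
    "dedup_probesets",
    "standard_contrasts",
    "DEAnalysis",
    "DEResults",
]

#: canonical treatment labels of the 3-block x 8-treatment design
DEFAULT_TREATMENTS = (
    "N2",
    "N2-hypoxia",
    "hif-1",
    "hif-1-hypoxia",
    "vhl-1",
    "rhy-1",
    "egl-9",
    "swan-1;vhl-1",
)

#: the four HIF-1-stabilizing mutant arms
MUTANTS = ("vhl-1", "rhy-1", "egl-9", "swan-1;vhl-1")


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for DE calling and downstream list statistics.

    fc_min is a linear fold change (1.6 means 1.6-fold either direction),
    q_max an estimated FDR, overlap_alpha the Fisher-test significance level
    for gene-list overlaps, enrichment_fdr the Bonferroni cut-off for
    category enrichment, and population_size the number of unique genes
    detected on the array.
    """

    fc_min: float = 1.6
    q_max: float = 0.05
    overlap_alpha: float = 0.001
    enrichment_fdr: float = 0.01
    population_size: int = 18011

    def __post_init__(self) -> None:
        if self.fc_min < 1:
            raise DataError("fc_min must be >= 1 (linear fold change)")
        for name in ("q_max", "overlap_alpha", "enrichment_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise DataError(f"{name} must be in (0, 1]")
        if self.population_size < 1:
            raise DataError("population_size must be positive")


@dataclass(frozen=True)
class ContrastSpec:
    """A zero-sum linear contrast of treatment means.

    ``weights`` maps treatment label -> contrast weight; omitted treatments
    get weight 0.
    """

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        total = float(sum(self.weights.values()))
        if abs(total) > 1e-9:
            raise DataError(
                f"contrast {self.name!r} weights sum to {total}, expected 0"
            )

    def vector(self, treatments: Sequence[str]) -> np.ndarray:
        unknown = set(self.weights) - set(treatments)
        if unknown:
            raise DataError(
                f"contrast {self.name!r} references unknown treatments {sorted(unknown)}"
            )
        return np.array([self.weights.get(t, 0.0) for t in treatments])


def standard_contrasts(mutants: Iterable[str] = MUTANTS) -> dict[str, ContrastSpec]:
    """The contrasts the analysis needs: per-genotype hypoxia effects, their
    interaction (HIF-1 dependence), and each HIF-1-stabilizing mutant vs N2."""
    specs = {
        "n2_hypoxia": ContrastSpec("n2_hypoxia", {"N2-hypoxia": 1.0, "N2": -1.0}),
        "hif1_hypoxia": ContrastSpec(
            "hif1_hypoxia", {"hif-1-hypoxia": 1.0, "hif-1": -1.0}
        ),
        "interaction": ContrastSpec(
            "interaction",
            {"N2-hypoxia": 1.0, "N2": -1.0, "hif-1-hypoxia": -1.0, "hif-1": 1.0},
        ),
    }
    for m in mutants:
        specs[f"mutant:{m}"] = ContrastSpec(f"mutant:{m}", {m: 1.0, "N2": -1.0})
    return specs


class ExpressionStudy:
    """Log2 expression matrix plus sample sheet for a balanced complete design.

    Parameters
    ----------
    matrix
        probesets x samples, log2 scale, no missing values.
    samples
        One row per sample with columns ``genotype``, ``treatment``,
        ``block``; index = sample labels matching the matrix columns.
    probe_map
        Optional many-to-many probeset->gene map with columns
        ``probeset``, ``gene``.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        samples: pd.DataFrame,
        probe_map: pd.DataFrame | None = None,
    ) -> None:
        required = {"treatment", "block"}
        if not required.issubset(samples.columns):
            raise DataError(f"sample sheet must have columns {sorted(required)}")
        if set(matrix.columns) != set(samples.index):
            raise DataError("matrix columns and sample sheet index disagree")
        if matrix.isna().any().any():
            raise DataError("expression matrix contains missing values")
        counts = samples.groupby(["treatment", "block"]).size()
        n_cells = samples["treatment"].nunique() * samples["block"].nunique()
        if (counts != 1).any() or len(samples) != n_cells:
            raise DataError(
                "design is not balanced complete: every (treatment, block) "
                "cell must contain exactly one sample"
            )
        self.samples = samples.copy()
        # column order: blocks within treatments, for reproducible layout
        order = samples.sort_values(["treatment", "block"]).index
        self.matrix = matrix.loc[:, order]
        self.probe_map = probe_map.copy() if probe_map is not None else None
        self.treatments = tuple(sorted(samples["treatment"].unique()))
        self.blocks = tuple(sorted(samples["block"].unique()))
        if len(self.blocks) < 2:
            raise DataError("at least 2 blocks are required for a residual term")


def fit_contrast(
    study: ExpressionStudy, contrast: ContrastSpec
) -> pd.DataFrame:
    """Test one zero-sum contrast per gene under the additive block+treatment model.

    Returns a DataFrame indexed like the matrix with columns ``estimate``
    (log2 units), ``F``, ``p`` and ``degenerate``.  In the balanced layout the
    least-squares estimate is the contrast applied to treatment means (each a
    mean over blocks), its variance is ``MSE * sum(w^2) / b``, and the F
    statistic has (1, (b-1)(t-1)) degrees of freedom.

    Genes with zero residual variance are flagged ``degenerate``: F is
    reported as +inf (or NaN when the estimate is 0) and p as NaN, and a
    warning is emitted.  They must be excluded from q-value input.
    """
    t, b = len(study.treatments), len(study.blocks)
    w = contrast.vector(study.treatments)
    y = study.matrix.to_numpy(dtype=float)  # genes x (t*b), ordered t-major
    n_genes = y.shape[0]
    cube = y.reshape(n_genes, t, b)

    treat_means = cube.mean(axis=2)  # genes x t
    block_means = cube.mean(axis=1)  # genes x b
    grand = cube.mean(axis=(1, 2))

    fitted = (
        treat_means[:, :, None] + block_means[:, None, :] - grand[:, None, None]
    )
    rss = ((cube - fitted) ** 2).sum(axis=(1, 2))
    df_resid = (b - 1) * (t - 1)
    mse = rss / df_resid

    estimate = treat_means @ w
    var_est = mse * float(w @ w) / b

    degenerate = mse <= 1e-12 * np.maximum(1.0, np.abs(grand))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = estimate**2 / var_est
        p = stats.f.sf(F, 1, df_resid)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero residual variance: "
            "F set to +inf sentinel, p undefined",
            stacklevel=2,
        )
        F = np.where(degenerate, np.inf, F)
        p = np.where(degenerate, np.nan, p)
    return pd.DataFrame(
        {"estimate": estimate, "F": F, "p": p, "degenerate": degenerate},
        index=study.matrix.index,
    )


# ---------------------------------------------------------------------------
# Storey-Tibshirani q-values


def estimate_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the null proportion pi0 from a p-value distribution.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on the grid
    lambda = 0, 0.05, ..., 0.90; a least-squares polynomial smoother with 3
    effective degrees of freedom is fitted through the (lambda, pi0(lambda))
    points and evaluated at the largest lambda; the result is clamped to
    (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.9001, 0.05)
    m = p.size
    if m < lambdas.size:
        warnings.warn("too few p-values to estimate pi0; using pi0 = 1", stacklevel=2)
        return 1.0
    pi0_lambda = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    coeffs = np.polyfit(lambdas, pi0_lambda, deg=2)
    pi0 = float(np.polyval(coeffs, lambdas[-1]))
    return min(max(pi0, 1.0 / m), 1.0)


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey-Tibshirani q-values.

    With ``pi0=1.0`` this reduces exactly to Benjamini-Hochberg adjusted
    p-values.  ``pi0=None`` estimates the null proportion via
    :func:`estimate_pi0`.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1] and be non-missing")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise DataError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# signed fold-change algebra


def signed_fc(delta_log2: float) -> float:
    """Back-transform a log2 difference to a signed fold change.

    The linear ratio r = 2**delta_log2 is returned as r when r >= 1 and as
    -1/r otherwise, so the magnitude is always >= 1 and the sign matches the
    direction of change.
    """
    r = 2.0**delta_log2
    return r if r >= 1.0 else -1.0 / r


def signed_to_linear(s: float) -> float:
    """Invert the signed convention back to a plain linear ratio."""
    if abs(s) < 1.0 - 1e-12:
        raise DataError(f"signed fold change {s} has magnitude < 1")
    return s if s >= 1.0 else -1.0 / s


def signed_ratio(s1: float, s2: float) -> float:
    """Ratio of two signed fold changes, in the signed convention.

    This is the "relative induction" statistic: the hypoxia induction in the
    wild type divided by the induction in the hif-1 mutant, both given as
    signed fold changes.
    """
    r = signed_to_linear(s1) / signed_to_linear(s2)
    return r if r >= 1.0 else -1.0 / r


# ---------------------------------------------------------------------------
# classification into regulated-gene lists


def classify(
    results: Mapping[str, pd.DataFrame],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Label genes from per-contrast test results.

    ``results`` maps contrast name -> DataFrame with columns ``estimate`` and
    ``q`` (gene-indexed).  Required contrasts: ``n2_hypoxia``,
    ``hif1_hypoxia``, ``interaction``; any ``mutant:<name>`` contrasts present
    are labelled analogously.

    Labels:

    * ``hypoxia_up`` / ``hypoxia_down`` — N2 hypoxia contrast significant
      (q <= q_max) with |signed FC| >= fc_min, sign deciding direction;
    * ``hif1_positive`` / ``hif1_negative`` — interaction contrast significant
      and relative induction (N2/hif-1) >= fc_min, resp. <= -fc_min;
    * ``mutant_up:<m>`` / ``mutant_down:<m>`` — per-mutant contrast vs N2.

    Returns a gene-indexed DataFrame of booleans per label plus signed-FC
    columns; genes flagged degenerate in a contrast are never labelled for it.
    """
    for req in ("n2_hypoxia", "hif1_hypoxia", "interaction"):
        if req not in results:
            raise DataError(f"missing required contrast {req!r}")
    genes = results["n2_hypoxia"].index
    out = pd.DataFrame(index=genes)
    sfc = np.vectorize(signed_fc)

    n2 = results["n2_hypoxia"]
    inter = results["interaction"]
    out["fc_n2"] = sfc(n2["estimate"].to_numpy())
    out["fc_hif1"] = sfc(results["hif1_hypoxia"]["estimate"].to_numpy())
    out["relative_induction"] = sfc(inter["estimate"].to_numpy())

    def _sig(df: pd.DataFrame) -> np.ndarray:
        ok = df["q"].to_numpy() <= thresholds.q_max
        if "degenerate" in df:
            ok &= ~df["degenerate"].to_numpy()
        return ok

    big = np.abs(out["fc_n2"].to_numpy()) >= thresholds.fc_min
    n2_sig = _sig(n2) & big
    out["hypoxia_up"] = n2_sig & (out["fc_n2"].to_numpy() > 0)
    out["hypoxia_down"] = n2_sig & (out["fc_n2"].to_numpy() < 0)

    int_sig = _sig(inter)
    ri = out["relative_induction"].to_numpy()
    out["hif1_positive"] = int_sig & (ri >= thresholds.fc_min)
    out["hif1_negative"] = int_sig & (ri <= -thresholds.fc_min)

    for name, df in results.items():
        if not name.startswith("mutant:"):
            continue
        m = name.split(":", 1)[1]
        fc = sfc(df["estimate"].to_numpy())
        sig = _sig(df) & (np.abs(fc) >= thresholds.fc_min)
        out[f"fc_mutant:{m}"] = fc
        out[f"mutant_up:{m}"] = sig & (fc > 0)
        out[f"mutant_down:{m}"] = sig & (fc < 0)
    return out


def labels_of(classified: pd.DataFrame, gene: str) -> tuple[str, ...]:
    """The sorted label set of one gene from a :func:`classify` table."""
    row = classified.loc[gene]
    return tuple(
        sorted(
            c
            for c in classified.columns
            if classified[c].dtype == bool and bool(row[c])
        )
    )


# ---------------------------------------------------------------------------
# probeset deduplication


def dedup_probesets(
    probe_map: pd.DataFrame, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Reduce a many-to-many probeset<->gene map to a one-to-one table.

    Probesets are visited in order of decreasing overall mean intensity
    (probeset id breaking ties); each is assigned to the lexicographically
    first of its annotated genes not yet taken.  The result is injective in
    both directions; the original map should be kept alongside for reference.
    """
    if probe_map is None or len(probe_map) == 0:
        raise DataError("empty probeset-gene mapping")
    if not {"probeset", "gene"}.issubset(probe_map.columns):
        raise DataError("probe_map needs columns 'probeset' and 'gene'")
    means = matrix.mean(axis=1)
    annotated = probe_map.groupby("probeset")["gene"].apply(sorted)
    order = sorted(
        annotated.index,
        key=lambda ps: (-means.get(ps, -np.inf), str(ps)),
    )
    taken_genes: set = set()
    rows = []
    for ps in order:
        for g in annotated[ps]:
            if g not in taken_genes:
                taken_genes.add(g)
                rows.append((ps, g))
                break
    return pd.DataFrame(rows, columns=["probeset", "gene"])


# ---------------------------------------------------------------------------
# Model/Results wrappers


class DEResults:
    """Results of a factorial DE analysis.

    Attributes
    ----------
    tests : dict of contrast name -> DataFrame (estimate, F, p, q)
    labels : gene-indexed classification table (see :func:`classify`)
    pi0 : dict of contrast name -> estimated null proportion
    """

    def __init__(self, tests, labels, pi0, thresholds):
        self.tests = tests
        self.labels = labels
        self.pi0 = pi0
        self.thresholds = thresholds

    def gene_lists(self) -> dict[str, list[str]]:
        """Gene lists per label, sorted."""
        return {
            c: sorted(self.labels.index[self.labels[c]])
            for c in self.labels.columns
            if self.labels[c].dtype == bool
        }

    def table(self, contrast: str) -> pd.DataFrame:
        """Per-gene report for one contrast: estimate, signed FC, F, p, q."""
        df = self.tests[contrast].copy()
        df.insert(1, "signed_fc", [signed_fc(e) for e in df["estimate"]])
        return df

    def summary(self) -> str:
        lines = [
            "Differential expression summary",
            f"  genes tested: {len(self.labels)}",
            f"  thresholds: q <= {self.thresholds.q_max}, "
            f"|FC| >= {self.thresholds.fc_min}",
        ]
        for name, n in sorted(
            (k, len(v)) for k, v in self.gene_lists().items()
        ):
            lines.append(f"  {name}: {n}")
        for c, v in self.pi0.items():
            lines.append(f"  pi0[{c}] = {v:.3f}")
        return "\n".join(lines)


class DEAnalysis:
    """statsmodels-style front door: build from an ExpressionStudy, call fit().

    ``fit`` runs every contrast, converts p to q per contrast (degenerate
    genes excluded from the q-value input and given q = NaN), and classifies.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        contrasts: Mapping[str, ContrastSpec] | None = None,
        thresholds: Thresholds = Thresholds(),
    ) -> None:
        self.study = study
        self.contrasts = dict(contrasts or standard_contrasts())
        self.thresholds = thresholds

    def fit(self, pi0: float | None = None) -> DEResults:
        tests: dict[str, pd.DataFrame] = {}
        pi0_used: dict[str, float] = {}
        for name, spec in self.contrasts.items():
            res = fit_contrast(self.study, spec)
            ok = ~res["degenerate"].to_numpy()
            q = np.full(len(res), np.nan)
            if ok.any():
                p_ok = res.loc[ok, "p"].to_numpy()
                this_pi0 = pi0 if pi0 is not None else estimate_pi0(p_ok)
                q[ok] = qvalues(p_ok, pi0=this_pi0)
                pi0_used[name] = this_pi0
            res["q"] = q
            tests[name] = res
        labels = classify(tests, self.thresholds)
        return DEResults(tests, labels, pi0_used, self.thresholds)
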