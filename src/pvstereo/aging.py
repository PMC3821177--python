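"""Three-step inference on density-vs-age data, statsmodels-style.

The procedure under test is a small-n cross-sectional aging analysis:

1.  split animals into middle-aged and aged groups at 65 human-equivalent
    years and compare group means with an unpaired t-test at alpha = 0.01;
2.  regress per-animal density on age and compute the Pearson
    product-moment correlation, requiring r > 0.7 AND parametric
    p <= 0.01;
3.  validate each regression with a Monte Carlo permutation test (1000
    re-assignments of densities to ages; p = fraction of shuffles with a
    permuted r at or beyond the observed r) at p <= 0.05.

A relationship is significant only if it passes BOTH the regression
criterion and the Monte Carlo criterion.  The permutation tail is
"signed" by default — literally "r_perm >= r_obs" — which makes a
negative observed correlation trivially non-extreme; an absolute-value
tail is available by flag, as a documented alternative rather than a
silent correction.

`PVAgingModel` bundles densities and demographics; `fit()` returns a
`PVAgingResults` carrying per-region regression, group-comparison and
ratio tables plus a `summary()`.  The underlying steps are module-level
functions usable on bare arrays.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .demographics import AGED, CUTOFF_HUMAN_YEARS, MIDDLE_AGED, prepare_demographics
from .regions import REGION_GROUPS, REGIONS

__all__ = [
    "RegressionResult",
    "GroupComparison",
    "aggregate_animal",
    "pearson_regression",
    "permutation_test",
    "dual_criterion",
    "group_ttest",
    "density_ratio",
    "observer_agreement",
    "PVAgingModel",
    "PVAgingResults",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Pearson regression of density on age, with permutation validation."""

    subdivision: str
    n: int
    r: float
    slope: float           # density units per monkey-year
    intercept: float
    p_param: float
    p_mc: float = float("nan")
    mc_iterations: int = 0
    r_cutoff: float = 0.7
    alpha_param: float = 0.01
    alpha_mc: float = 0.05

    @property
    def passes_regression(self) -> bool:
        return bool(self.r > self.r_cutoff and self.p_param <= self.alpha_param)

    @property
    def passes_mc(self) -> bool:
        return bool(self.p_mc <= self.alpha_mc)

    @property
    def significant(self) -> bool:
        return dual_criterion(self.r, self.p_param, self.p_mc,
                              r_cutoff=self.r_cutoff,
                              alpha_param=self.alpha_param,
                              alpha_mc=self.alpha_mc)


@dataclass
class GroupComparison:
    subdivision: str
    mean_middle: float
    mean_aged: float
    n_middle: int
    n_aged: int
    t_stat: float
    p_value: float
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return bool(self.p_value <= self.alpha)


def _validated_xy(ages, densities):
    x = np.asarray(ages, dtype=float)
    y = np.asarray(densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("ages and densities must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError(f"need n >= 3 animals, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate input: zero variance in ages or densities")
    return x, y


def aggregate_animal(densities: pd.DataFrame,
                     value_col: str = "density_per_mm3") -> pd.DataFrame:
    """Collapse repeated measures to one unweighted mean per animal x
    subdivision.  The downstream tests operate on animals, not
    measurements, so this is the unit-of-analysis reduction.

    Animals missing a subdivision get a row with a missing value and a
    warning (no silent drops).
    """
    if densities.empty:
        raise ValueError("empty density table")
    agg = (
        densities.groupby(["animal_id", "subdivision"], sort=True)[value_col]
        .mean()
        .rename(value_col)
    )
    full = pd.MultiIndex.from_product(
        [densities["animal_id"].unique(), densities["subdivision"].unique()],
        names=["animal_id", "subdivision"],
    ).sortlevel()[0]
    out = agg.reindex(full).reset_index()
    missing = out[out[value_col].isna()]
    if len(missing):
        warnings.warn(
            "missing subdivisions for some animals: "
            f"{missing[['animal_id', 'subdivision']].to_dict('records')}",
            stacklevel=2,
        )
    return out


def pearson_regression(ages, densities, *, subdivision: str = "",
                       r_cutoff: float = 0.7, alpha_param: float = 0.01,
                       alpha_mc: float = 0.05) -> RegressionResult:
    """Least-squares line and Pearson r with the parametric two-sided p
    from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x, y = _validated_xy(ages, densities)
    fit = stats.linregress(x, y)
    return RegressionResult(
        subdivision=subdivision, n=len(x), r=float(fit.rvalue),
        slope=float(fit.slope), intercept=float(fit.intercept),
        p_param=float(fit.pvalue), r_cutoff=r_cutoff,
        alpha_param=alpha_param, alpha_mc=alpha_mc,
    )


def _pearson_r_rows(x: np.ndarray, ymat: np.ndarray) -> np.ndarray:
    """Pearson r of x against each row of ymat (rows are permutations of
    the same vector, so row means/variances are constant, but this is
    computed generally)."""
    xc = x - x.mean()
    yc = ymat - ymat.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * np.einsum("ij,ij->i", yc, yc))
    return num / den


def permutation_test(ages, densities, n_iter: int = 1000, seed=None,
                     tail: str = "signed", *, plus_one: bool = False) -> float:
    """Monte Carlo permutation p for the Pearson correlation.

    Shuffles the density vector against the fixed age vector ``n_iter``
    times; p is the fraction of shuffles whose r is at or beyond the
    observed r.  ``tail='signed'`` counts r_perm >= r_obs (the literal
    procedure); ``tail='absolute'`` counts |r_perm| >= |r_obs|.  With
    ``plus_one`` the small-sample (k+1)/(n+1) correction is applied;
    by default the count is divided by n_iter exactly.
    """
    x, y = _validated_xy(ages, densities)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if tail not in ("signed", "absolute"):
        raise ValueError("tail must be 'signed' or 'absolute'")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    r_obs = float(_pearson_r_rows(x, y[None, :])[0])
    perms = rng.permuted(np.tile(y, (n_iter, 1)), axis=1)
    r_perm = _pearson_r_rows(x, perms)
    tol = 1e-12
    if tail == "signed":
        k = int(np.count_nonzero(r_perm >= r_obs - tol))
    else:
        k = int(np.count_nonzero(np.abs(r_perm) >= abs(r_obs) - tol))
    if plus_one:
        return (k + 1) / (n_iter + 1)
    return k / n_iter


def dual_criterion(r: float, p_param: float, p_mc: float, *,
                   r_cutoff: float = 0.7, alpha_param: float = 0.01,
                   alpha_mc: float = 0.05) -> bool:
    """Significant iff r > r_cutoff AND p_param <= alpha_param AND
    p_mc <= alpha_mc — the conjunction of the regression criterion and
    the Monte Carlo criterion."""
    return bool(r > r_cutoff and p_param <= alpha_param and p_mc <= alpha_mc)


def group_ttest(middle, aged, alpha: float = 0.01, *, welch: bool = False,
                subdivision: str = "") -> GroupComparison:
    """Unpaired two-sample t-test between age groups.

    Student's pooled-variance test by default (the generic unpaired
    t-test); Welch's unequal-variance variant by flag.
    """
    m = np.asarray(middle, dtype=float)
    a = np.asarray(aged, dtype=float)
    if len(m) < 2 or len(a) < 2:
        raise ValueError(
            f"each group needs n >= 2 (got {len(m)} middle-aged, "
            f"{len(a)} aged)"
        )
    if np.ptp(m) == 0 and np.ptp(a) == 0 and m.mean() == a.mean():
        t, p = 0.0, 1.0  # identical constant groups: no evidence at all
    else:
        t, p = stats.ttest_ind(m, a, equal_var=not welch)
    return GroupComparison(
        subdivision=subdivision,
        mean_middle=float(m.mean()), mean_aged=float(a.mean()),
        n_middle=len(m), n_aged=len(a),
        t_stat=float(t), p_value=float(p), alpha=alpha,
    )


def density_ratio(aged, middle) -> float:
    """mean(aged) / mean(middle-aged): the fold-change normalization.
    A ratio above 1 indicates an age-related density increase."""
    a = np.asarray(aged, dtype=float)
    m = np.asarray(middle, dtype=float)
    if len(a) == 0 or len(m) == 0:
        raise ValueError("both groups must be non-empty")
    mm = m.mean()
    if mm == 0:
        raise ValueError("middle-aged mean is zero; ratio undefined")
    return float(a.mean() / mm)


def observer_agreement(counts_a, counts_b, *, threshold: float = 0.95,
                       run_length: int = 20):
    """Inter-observer calibration on paired per-section counts.

    Per-section agreement is 1 - |A - B| / max(A, B) (1 when both are
    zero).  The run criterion is met iff some window of ``run_length``
    consecutive sections all reach ``threshold``.  Also returns the
    paired t-test p between observers (1.0 when the counts are
    identical, reported as "no difference").

    Returns (agreements, criterion_met, paired_p).
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired count vectors must have equal length")
    mx = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        agreement = np.where(mx > 0, 1.0 - np.abs(a - b) / mx, 1.0)
    ok = agreement >= threshold
    met = False
    if len(ok) >= run_length:
        window_sums = np.convolve(ok.astype(int), np.ones(run_length, int),
                                  "valid")
        met = bool((window_sums == run_length).any())
    diffs = a - b
    if np.allclose(diffs, 0.0):
        p = 1.0  # identical counts: reported as "no difference"
    elif len(a) < 2 or np.ptp(diffs) == 0:
        p = float("nan")  # constant non-zero difference: t undefined
    else:
        p = float(stats.ttest_rel(a, b).pvalue)
    return agreement, met, p


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class PVAgingModel:
    """Aging analysis of per-region neuron densities for one cohort.

    Parameters
    ----------
    densities : DataFrame
        Columns animal_id, subdivision, density_per_mm3 (possibly many
        rows per animal x subdivision; they are averaged).
    demographics : DataFrame
        Columns animal_id, age_months (plus optional human_age_years,
        sex, thickness_um).  Groups are derived from age.
    regions : sequence of str, optional
        Regions to analyze; defaults to those present, in canonical
        order, plus the pooled magno/parvocellular layer groups where
        all member layers are present.
    cutoff_human_years : float
        Age-group cutoff (65 human-equivalent years = 21.66 monkey
        years).
    """

    def __init__(self, densities: pd.DataFrame, demographics: pd.DataFrame,
                 regions=None, region_groups: dict | None = None,
                 cutoff_human_years: float = CUTOFF_HUMAN_YEARS):
        self.demographics = prepare_demographics(demographics,
                                                 cutoff_human_years)
        self.per_animal = aggregate_animal(densities)
        known = set(self.per_animal["subdivision"].unique())
        orphans = set(self.per_animal["animal_id"]) - \
            set(self.demographics["animal_id"])
        if orphans:
            raise ValueError(
                f"density rows reference animals missing from the "
                f"demographics table: {sorted(orphans)}"
            )
        if regions is None:
            regions = [r for r in REGIONS if r in known]
        self.regions = list(regions)
        if region_groups is None:
            region_groups = {
                name: members for name, members in REGION_GROUPS.items()
                if set(members) <= known
            }
        self.region_groups = dict(region_groups)
        self.cutoff_human_years = cutoff_human_years

        wide = self.per_animal.pivot(index="animal_id",
                                     columns="subdivision",
                                     values="density_per_mm3")
        for name, members in self.region_groups.items():
            wide[name] = wide[list(members)].mean(axis=1)
        self._wide = wide.join(
            self.demographics.set_index("animal_id")[
                ["age_monkey_years", "human_age_years", "group"]
            ]
        )

    @classmethod
    def from_csv(cls, densities_path, demographics_path, **kwargs
                 ) -> "PVAgingModel":
        return cls(pd.read_csv(densities_path),
                   pd.read_csv(demographics_path), **kwargs)

    def fit(self, mc_iterations: int = 1000, seed: int = 0,
            tail: str = "signed", *, r_cutoff: float = 0.7,
            alpha_regression: float = 0.01, alpha_mc: float = 0.05,
            alpha_ttest: float = 0.01, welch: bool = False,
            plus_one: bool = False) -> "PVAgingResults":
        """Run the full three-step procedure for every region.

        Randomness (the permutation re-assignments) derives from a
        single seed split per region, so region results are individually
        reproducible and independent of analysis order.
        """
        all_regions = self.regions + list(self.region_groups)
        seqs = np.random.SeedSequence(seed).spawn(len(all_regions))
        wide = self._wide
        is_aged = wide["group"] == AGED
        reg_rows, cmp_rows, ratio_rows = [], [], []

        for region, seq in zip(all_regions, seqs):
            x = wide["age_monkey_years"].to_numpy()
            y = wide[region].to_numpy()
            if np.isnan(y).any():
                bad = wide.index[np.isnan(y)].tolist()
                raise ValueError(
                    f"missing density for region {region!r}, animals {bad}"
                )
            res = pearson_regression(
                x, y, subdivision=region, r_cutoff=r_cutoff,
                alpha_param=alpha_regression, alpha_mc=alpha_mc)
            res.p_mc = permutation_test(
                x, y, n_iter=mc_iterations,
                seed=np.random.default_rng(seq), tail=tail,
                plus_one=plus_one)
            res.mc_iterations = mc_iterations
            reg_rows.append({
                "subdivision": region, "n": res.n, "r": res.r,
                "slope_per_monkey_year": res.slope,
                "slope_per_human_year": res.slope / 3.0,
                "intercept": res.intercept, "p_param": res.p_param,
                "p_mc": res.p_mc, "mc_iterations": mc_iterations,
                "passes_regression": res.passes_regression,
                "passes_mc": res.passes_mc,
                "significant": res.significant,
            })

            aged_vals = wide.loc[is_aged, region].to_numpy()
            mid_vals = wide.loc[~is_aged, region].to_numpy()
            cmp = group_ttest(mid_vals, aged_vals, alpha=alpha_ttest,
                              welch=welch, subdivision=region)
            cmp_rows.append({
                "subdivision": region,
                "mean_middle": cmp.mean_middle, "mean_aged": cmp.mean_aged,
                "n_middle": cmp.n_middle, "n_aged": cmp.n_aged,
                "t_stat": cmp.t_stat, "p_value": cmp.p_value,
                "significant": cmp.significant,
            })
            ratio_rows.append({
                "subdivision": region,
                "ratio_aged_over_middle": density_ratio(aged_vals, mid_vals),
            })

        params = {
            "mc_iterations": mc_iterations, "seed": seed, "tail": tail,
            "r_cutoff": r_cutoff, "alpha_regression": alpha_regression,
            "alpha_mc": alpha_mc, "alpha_ttest": alpha_ttest,
            "welch": welch, "plus_one": plus_one,
            "cutoff_human_years": self.cutoff_human_years,
        }
        return PVAgingResults(
            model=self,
            regressions=pd.DataFrame(reg_rows),
            group_comparisons=pd.DataFrame(cmp_rows),
            ratios=pd.DataFrame(ratio_rows),
            params=params,
        )


class PVAgingResults:
    """Fitted aging analysis: per-region tables plus run parameters."""

    def __init__(self, model: PVAgingModel, regressions: pd.DataFrame,
                 group_comparisons: pd.DataFrame, ratios: pd.DataFrame,
                 params: dict):
        self.model = model
        self.regressions = regressions
        self.group_comparisons = group_comparisons
        self.ratios = ratios
        self.params = params

    @property
    def significant_regions(self) -> list[str]:
        sel = self.regressions["significant"]
        return self.regressions.loc[sel, "subdivision"].tolist()

    def summary(self) -> str:
        p = self.params
        lines = [
            "Parvalbumin density vs age — three-step analysis",
            "=" * 64,
            f"animals: {len(self.model._wide)}   "
            f"groups: {int((self.model._wide['group'] == MIDDLE_AGED).sum())}"
            f" middle-aged / {int((self.model._wide['group'] == AGED).sum())}"
            f" aged (cutoff {p['cutoff_human_years']:g} human-equiv years)",
            f"criteria: r > {p['r_cutoff']:g} & p <= {p['alpha_regression']:g}"
            f" (regression); p <= {p['alpha_mc']:g} "
            f"(Monte Carlo, {p['mc_iterations']} reassignments, "
            f"{p['tail']} tail); t-test alpha {p['alpha_ttest']:g}",
            "",
            f"{'region':>10} {'r':>7} {'p_param':>9} {'p_mc':>7} "
            f"{'slope/yr':>9} {'sig':>4}   {'t':>7} {'p_t':>8} "
            f"{'ratio':>6}",
        ]
        gc = self.group_comparisons.set_index("subdivision")
        rt = self.ratios.set_index("subdivision")
        for row in self.regressions.itertuples(index=False):
            g = gc.loc[row.subdivision]
            lines.append(
                f"{row.subdivision:>10} {row.r:7.3f} {row.p_param:9.4f} "
                f"{row.p_mc:7.3f} {row.slope_per_monkey_year:9.1f} "
                f"{'yes' if row.significant else 'no':>4}   "
                f"{g.t_stat:7.2f} {g.p_value:8.4f} "
                f"{rt.loc[row.subdivision, 'ratio_aged_over_middle']:6.2f}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write regression/group/ratio TSVs and a JSON run log."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
        self.group_comparisons.to_csv(out / "group_comparisons.tsv",
                                      sep="\t", index=False)
        self.ratios.to_csv(out / "ratios.tsv", sep="\t", index=False)
        with open(out / "run_log.json", "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
            fh.write("\n")
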