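"""Replicate-level phenotype statistics for the two-treatment MAGIC trials.

Covers the classical quantitative-genetics workflow for a genotype panel
evaluated under a control and a stress treatment within an experiment:

* two-way ANOVA, Y = mu + G + T + GxT + error, with sequential (Type I)
  sums of squares in the order G, T, GxT and the percentage of total SSq
  attributed to each term;
* broad-sense heritability h2 = s2G / (s2G + s2E / r) from the one-way
  genotype ANOVA, r being the average number of replicates per genotype;
* per-genotype phenotypic plasticity PP = (stress - control) / control on
  replicate means, with a log-difference variant for log-flagged traits;
* population-level mean relative variation (MV), the percent change of the
  trait mean between treatments;
* Pearson correlations between traits within treatment and per trait
  between treatments.

Traits flagged ``log`` (typically fruit weight and fruit number) are
log-transformed before ANOVA, heritability and correlation computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PhenotypeTable",
    "AnovaResult",
    "HeritabilityResult",
    "PhenoError",
    "two_way_anova",
    "heritability",
    "plasticity",
    "mean_relative_variation",
    "relative_variation",
    "correlations",
]

KEY = ["line", "experiment", "treatment", "replicate", "trait"]


class PhenoError(ValueError):
    """Invalid phenotype input."""


@dataclass(frozen=True)
class PhenotypeTable:
    """Long-format replicate-level phenotypes with per-trait transform flags."""

    data: pd.DataFrame
    log_traits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        missing = [c for c in KEY + ["value"] if c not in self.data.columns]
        if missing:
            raise PhenoError(f"phenotype table missing columns: {missing}")
        if self.data.duplicated(KEY).any():
            row = self.data[self.data.duplicated(KEY)].iloc[0]
            raise PhenoError(
                f"duplicate phenotype key: {tuple(row[k] for k in KEY)}"
            )
        for t in self.log_traits:
            v = self.data.loc[self.data["trait"] == t, "value"].dropna()
            if (v <= 0).any():
                raise PhenoError(f"log transform on non-positive trait {t!r}")
        object.__setattr__(self, "log_traits", frozenset(self.log_traits))

    def transformed(self, trait: str, experiment: str) -> pd.DataFrame:
        """Rows for one trait+experiment with the trait's transform applied."""
        d = self.data[
            (self.data["trait"] == trait) & (self.data["experiment"] == experiment)
        ].copy()
        if trait in self.log_traits:
            d["value"] = np.log(d["value"])
        return d

    def line_means(self, trait: str, experiment: str, treatment: str) -> pd.Series:
        """Per-line replicate means after transform, indexed by line id."""
        d = self.transformed(trait, experiment)
        d = d[d["treatment"] == treatment]
        return d.groupby("line")["value"].mean()

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())

    @property
    def experiments(self) -> list[str]:
        return sorted(self.data["experiment"].unique())

    def treatments(self, experiment: str) -> list[str]:
        return sorted(
            self.data.loc[self.data["experiment"] == experiment, "treatment"].unique()
        )


@dataclass(frozen=True)
class AnovaResult:
    """Sequential two-way ANOVA decomposition for one trait+experiment."""

    trait: str
    experiment: str
    terms: pd.DataFrame  # index: G, T, GxT, residual; columns: ss, df, F, p, ss_pct

    def __post_init__(self) -> None:
        ss = self.terms["ss"]
        if (ss < -1e-12).any():
            raise PhenoError("negative sum of squares")
        if ss.sum() > 0 and abs(self.terms["ss_pct"].sum() - 100.0) > 1e-6:
            raise PhenoError("SSq percentages do not sum to 100")


@dataclass(frozen=True)
class HeritabilityResult:
    trait: str
    experiment: str
    treatment: str
    sigma2_g: float
    sigma2_e: float
    r: float
    h2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise PhenoError("negative variance component")
        denom = self.sigma2_g + self.sigma2_e / self.r
        object.__setattr__(self, "h2", self.sigma2_g / denom if denom > 0 else 0.0)


def two_way_anova(table: PhenotypeTable, trait: str, experiment: str) -> AnovaResult:
    """Two-way fixed-effect ANOVA Y = mu + G + T + GxT + error.

    Sequential (Type I) sums of squares are taken in the order genotype,
    treatment, interaction; F statistics are against the residual mean
    square.  With no residual degrees of freedom (single replicate) or a
    perfectly fitted response, F and p are reported as NaN.
    """
    d = table.transformed(trait, experiment).dropna(subset=["value"])
    treatments = d["treatment"].unique()
    if len(treatments) < 2:
        raise PhenoError(f"need >=2 treatments, found {list(treatments)}")
    if d["line"].nunique() < 2:
        raise PhenoError("need >=2 genotypes")
    if np.allclose(d["value"], d["value"].iloc[0]):
        # degenerate: no variation at all -> zero SSq, F undefined
        terms = pd.DataFrame(
            {
                "ss": 0.0,
                "df": [d["line"].nunique() - 1, len(treatments) - 1,
                       (d["line"].nunique() - 1) * (len(treatments) - 1),
                       np.nan],
                "F": np.nan,
                "p": np.nan,
                "ss_pct": 0.0,
            },
            index=["G", "T", "GxT", "residual"],
        )
        return AnovaResult(trait=trait, experiment=experiment, terms=terms)
    model = smf.ols("value ~ C(line) + C(treatment) + C(line):C(treatment)", data=d).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # anova_lm warns on 0-df residuals
        aov = sm.stats.anova_lm(model, typ=1)
    aov.index = ["G", "T", "GxT", "residual"]
    total = aov["sum_sq"].sum()
    terms = pd.DataFrame(
        {
            "ss": aov["sum_sq"],
            "df": aov["df"],
            "F": aov["F"],
            "p": aov["PR(>F)"],
            "ss_pct": aov["sum_sq"] / total * 100.0 if total > 0 else 0.0,
        }
    )
    return AnovaResult(trait=trait, experiment=experiment, terms=terms)


def heritability(
    table: PhenotypeTable,
    trait: str,
    experiment: str,
    treatment: str,
    r_mode: str = "arithmetic",
) -> HeritabilityResult:
    """Broad-sense heritability from the one-way genotype ANOVA.

    s2E is the residual mean square, s2G = (MS_genotype - s2E) / r truncated
    at zero, and r is the average replicate count per genotype (arithmetic
    mean by default, harmonic behind the flag).
    """
    d = table.transformed(trait, experiment)
    d = d[d["treatment"] == treatment].dropna(subset=["value"])
    counts = d.groupby("line")["value"].count()
    if len(counts) < 2:
        raise PhenoError("need >=2 genotypes for heritability")
    if r_mode == "arithmetic":
        r = float(counts.mean())
    elif r_mode == "harmonic":
        r = float(scipy.stats.hmean(counts))
    else:
        raise PhenoError(f"unknown r_mode {r_mode!r}")
    n = len(d)
    k = len(counts)
    grand = d["value"].mean()
    means = d.groupby("line")["value"].transform("mean")
    ss_g = float(((means - grand) ** 2).sum())
    ss_e = float(((d["value"] - means) ** 2).sum())
    df_e = n - k
    if df_e <= 0:
        # single replicate everywhere: genetic and residual variance
        # are confounded; report all variance as genetic with s2E = 0
        ms_g = ss_g / (k - 1)
        return HeritabilityResult(trait, experiment, treatment, ms_g, 0.0, r)
    ms_g = ss_g / (k - 1)
    ms_e = ss_e / df_e
    s2g = max((ms_g - ms_e) / r, 0.0)
    return HeritabilityResult(trait, experiment, treatment, s2g, ms_e, r)


def plasticity(
    table: PhenotypeTable,
    trait: str,
    experiment: str,
    control: str,
    stress: str,
) -> pd.DataFrame:
    """Per-line phenotypic plasticity between a stress and its control.

    PP = (stress_mean - control_mean) / control_mean on untransformed
    replicate means.  For traits flagged log, the value used as the QTL
    plasticity trait is the log-mean difference log(stress) - log(control)
    (relative change cannot be log-transformed once negative); both columns
    are returned, ``qtl_value`` holding the one meant for mapping.
    Lines with a zero control mean get NaN and a warning.
    """
    raw = table.data[
        (table.data["trait"] == trait) & (table.data["experiment"] == experiment)
    ]
    means = raw.groupby(["line", "treatment"])["value"].mean().unstack()
    for tr in (control, stress):
        if tr not in means.columns:
            raise PhenoError(f"treatment {tr!r} absent for {trait!r}/{experiment!r}")
    both = means.dropna(subset=[control, stress])
    zero = both[control] == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} line(s) with zero control mean for {trait!r}; PP undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pp = np.where(zero, np.nan, (both[stress] - both[control]) / both[control])
    if trait in table.log_traits:
        qtl_value = np.log(both[stress].to_numpy()) - np.log(both[control].to_numpy())
    else:
        qtl_value = pp
    return pd.DataFrame(
        {
            "line": both.index,
            "experiment": experiment,
            "trait": trait,
            "pp": pp,
            "qtl_value": qtl_value,
        }
    ).reset_index(drop=True)


def relative_variation(reference_mean: float, target_mean: float) -> float:
    """Percent change of a target mean against a reference mean."""
    if reference_mean == 0:
        raise PhenoError("reference mean is zero")
    return (target_mean - reference_mean) / reference_mean * 100.0


def mean_relative_variation(
    table: PhenotypeTable,
    trait: str,
    reference: tuple[str, str],
    target: tuple[str, str],
    paired: bool = True,
) -> float:
    """Mean relative variation (MV, %) of a trait between two treatments.

    ``reference`` and ``target`` are (experiment, treatment) pairs, so the
    comparison can cross experiments (e.g. salinity vs the first year's
    control).  With ``paired`` (default), means are taken over the lines
    common to both conditions; otherwise over all lines per condition.
    Untransformed values are used: MV describes the raw trait scale.
    """
    def cond_means(exp: str, tr: str) -> pd.Series:
        d = table.data[
            (table.data["trait"] == trait)
            & (table.data["experiment"] == exp)
            & (table.data["treatment"] == tr)
        ]
        if d.empty:
            raise PhenoError(f"no data for {trait!r} in {exp!r}/{tr!r}")
        return d.groupby("line")["value"].mean()

    ref = cond_means(*reference)
    tgt = cond_means(*target)
    if paired:
        common = ref.index.intersection(tgt.index)
        if len(common) == 0:
            raise PhenoError("no common lines between conditions")
        ref, tgt = ref[common], tgt[common]
    return relative_variation(float(ref.mean()), float(tgt.mean()))


def correlations(table: PhenotypeTable, experiment: str) -> pd.DataFrame:
    """Pearson correlations on per-line means (after transform).

    Returns tidy rows for (a) every trait pair within each treatment and
    (b) every trait between the experiment's treatments; columns: kind,
    treatment_a, trait_a, treatment_b, trait_b, r, p, n.  Pairs with fewer
    than 3 common lines or zero variance are reported with NaN.
    """
    traits = table.traits
    treatments = table.treatments(experiment)
    means = {
        (tr, t): table.line_means(t, experiment, tr)
        for tr in treatments
        for t in traits
        if not table.line_means(t, experiment, tr).empty
    }
    rows = []

    def corr(a: pd.Series, b: pd.Series) -> tuple[float, float, int]:
        common = a.index.intersection(b.index)
        x, y = a[common].to_numpy(float), b[common].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return np.nan, np.nan, len(x)
        r, p = scipy.stats.pearsonr(x, y)
        return float(r), float(p), len(x)

    for tr in treatments:
        for i, ta in enumerate(traits):
            for tb in traits[i + 1 :]:
                if (tr, ta) in means and (tr, tb) in means:
                    r, p, n = corr(means[(tr, ta)], means[(tr, tb)])
                    rows.append(("within", tr, ta, tr, tb, r, p, n))
    if len(treatments) == 2:
        t0, t1 = treatments
        for t in traits:
            if (t0, t) in means and (t1, t) in means:
                r, p, n = corr(means[(t0, t)], means[(t1, t)])
                rows.append(("between", t0, t, t1, t, r, p, n))
    return pd.DataFrame(
        rows,
        columns=["kind", "treatment_a", "trait_a", "treatment_b", "trait_b", "r", "p", "n"],
    )
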