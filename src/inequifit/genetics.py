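"""Genotype coding and gene–preference association statistics.

Covers the genetic half of the pipeline:

* AVPR1A RS3 microsatellite coding — alleles are fragment lengths in bp,
  dichotomised short/long at the sample-median threshold of 330 bp
  (< 330 = S, >= 330 = L), giving SS/SL/LL genotypes; the 334 bp allele is
  additionally tracked as a specific carrier coding.
* Hardy–Weinberg equilibrium and genotype-independence chi-square tests.
* ANCOVA of a per-participant preference estimate (DIA or AIA) on the three
  genotype factors simultaneously, with age as a covariate: Type-III
  marginal F tests (sum-to-zero factor coding), partial eta squared, and
  Bonferroni-corrected pairwise comparisons of covariate-adjusted means
  with Cohen's d on the root-MSE scale.

Model fitting goes through statsmodels OLS on an explicitly constructed
design matrix, so the factor coding and contrast definitions are visible
here rather than buried in a formula engine.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InvalidInputError

__all__ = [
    "RS3_THRESHOLD_BP",
    "RS3_RISK_ALLELE_BP",
    "GenotypeCounts",
    "HweResult",
    "FactorTest",
    "PairwiseContrast",
    "AssociationResult",
    "classify_rs3_allele",
    "rs3_genotype",
    "carrier_334",
    "add_derived_genotypes",
    "genotype_counts",
    "hwe_chisq",
    "crosstab_chisq",
    "ancova",
    "pairwise_bonferroni",
    "pearson_corr",
    "genotype_report",
]

#: Median split point for RS3 allele lengths: < 330 bp is S, >= 330 bp is L.
RS3_THRESHOLD_BP = 330
#: The specific long allele examined as a carrier coding.
RS3_RISK_ALLELE_BP = 334

SNP_GENOTYPES = ("AA", "AG", "GG")
RS3_GENOTYPES = ("SS", "SL", "LL")

GENOTYPE_COLUMNS = {
    "oxtr": SNP_GENOTYPES,
    "avpr1a_rs3": RS3_GENOTYPES,
    "oprm1": SNP_GENOTYPES,
}


def classify_rs3_allele(length_bp: int, threshold_bp: int = RS3_THRESHOLD_BP) -> str:
    """'S' for alleles shorter than the threshold, 'L' otherwise."""
    if length_bp <= 0:
        raise InvalidInputError(f"allele length must be positive, got {length_bp}")
    return "S" if length_bp < threshold_bp else "L"


def rs3_genotype(a1_bp: int, a2_bp: int, threshold_bp: int = RS3_THRESHOLD_BP) -> str:
    """SS/SL/LL from the two allele lengths (order-insensitive)."""
    pair = sorted(classify_rs3_allele(a, threshold_bp) for a in (a1_bp, a2_bp))
    return {("L", "L"): "LL", ("L", "S"): "SL", ("S", "S"): "SS"}[tuple(pair)]


def carrier_334(a1_bp: int, a2_bp: int) -> bool:
    """True when either allele is exactly the 334 bp risk allele."""
    if a1_bp <= 0 or a2_bp <= 0:
        raise InvalidInputError("allele lengths must be positive")
    return RS3_RISK_ALLELE_BP in (a1_bp, a2_bp)


def add_derived_genotypes(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Append ``avpr1a_rs3`` (SS/SL/LL) and ``carrier_334`` columns.

    Expects ``avpr1a_allele1_bp``/``avpr1a_allele2_bp`` integer columns.
    """
    need = {"avpr1a_allele1_bp", "avpr1a_allele2_bp"}
    missing = need - set(genotypes.columns)
    if missing:
        raise DataError(f"genotype table is missing columns: {sorted(missing)}")
    out = genotypes.copy()
    out["avpr1a_rs3"] = [
        rs3_genotype(a1, a2)
        for a1, a2 in zip(out["avpr1a_allele1_bp"], out["avpr1a_allele2_bp"])
    ]
    out["carrier_334"] = [
        carrier_334(a1, a2)
        for a1, a2 in zip(out["avpr1a_allele1_bp"], out["avpr1a_allele2_bp"])
    ]
    return out


class GenotypeCounts(NamedTuple):
    """Ordered biallelic genotype counts (hom1, het, hom2)."""

    hom1: int
    het: int
    hom2: int

    @property
    def total(self) -> int:
        return self.hom1 + self.het + self.hom2


class HweResult(NamedTuple):
    chi2: float
    df: int
    p: float


def genotype_counts(values: Sequence[str], order: Sequence[str]) -> GenotypeCounts:
    """Count genotypes in the given (hom1, het, hom2) order."""
    if len(order) != 3:
        raise InvalidInputError("order must name three genotypes")
    counter = pd.Series(values).value_counts()
    unknown = set(counter.index) - set(order)
    if unknown:
        raise DataError(f"unexpected genotypes {sorted(unknown)}; expected {order}")
    return GenotypeCounts(*(int(counter.get(g, 0)) for g in order))


def hwe_chisq(counts: GenotypeCounts) -> HweResult:
    """Pearson goodness-of-fit test against Hardy–Weinberg proportions.

    The allele frequency is estimated from the counts; expected counts are
    (p^2 n, 2pq n, q^2 n); 1 degree of freedom (3 cells − 1 − 1 estimated
    frequency); no continuity correction.  Monomorphic samples return
    chi2 = 0 with a warning (the test is vacuous there).
    """
    n = counts.total
    if n <= 0:
        raise InvalidInputError("need at least one genotype")
    p = (2 * counts.hom1 + counts.het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        warnings.warn("monomorphic sample: HWE test is vacuous", stacklevel=2)
        return HweResult(0.0, 1, 1.0)
    expected = np.array([p * p * n, 2 * p * q * n, q * q * n])
    observed = np.array(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2, 1, float(stats.chi2.sf(chi2, 1)))


def crosstab_chisq(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson independence chi-square on a genotype cross-table (no Yates)."""
    table = np.asarray(table, dtype=float)
    if table.sum() <= 0:
        raise InvalidInputError("empty contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# ANCOVA


@dataclass(frozen=True)
class FactorTest:
    factor: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float


@dataclass(frozen=True)
class PairwiseContrast:
    factor: str
    level_a: str
    level_b: str
    estimate: float  # adjusted-mean difference (a − b)
    t: float
    df: int
    p: float
    bonferroni_threshold: float
    cohen_d: float


@dataclass(frozen=True)
class AssociationResult:
    dependent: str
    n: int
    df_den: int
    mse: float
    factor_tests: tuple[FactorTest, ...]
    contrasts: tuple[PairwiseContrast, ...]

    def factor(self, name: str) -> FactorTest:
        for ft in self.factor_tests:
            if ft.factor == name:
                return ft
        raise KeyError(name)

    def factors_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dependent": self.dependent,
                    "factor": f.factor,
                    "F": f.F,
                    "df_num": f.df_num,
                    "df_den": f.df_den,
                    "p": f.p,
                    "partial_eta2": f.partial_eta2,
                }
                for f in self.factor_tests
            ]
        )

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "dependent": self.dependent,
                    "factor": c.factor,
                    "level_a": c.level_a,
                    "level_b": c.level_b,
                    "estimate": c.estimate,
                    "t": c.t,
                    "df": c.df,
                    "p": c.p,
                    "bonferroni_threshold": c.bonferroni_threshold,
                    "cohen_d": c.cohen_d,
                }
                for c in self.contrasts
            ]
        )


class _Design:
    """Sum-to-zero-coded design matrix with named column blocks."""

    def __init__(self, data: pd.DataFrame, factors, covariates, interactions):
        self.columns = ["Intercept"]
        cols = [np.ones(len(data))]
        self.blocks: dict[str, list[int]] = {}
        self.levels: dict[str, list[str]] = {}
        self.level_codes: dict[str, dict[str, np.ndarray]] = {}

        def add_factor(name: str, values: pd.Series):
            levels = sorted(values.astype(str).unique())
            if len(levels) < 2:
                raise InvalidInputError(
                    f"factor {name!r} needs >= 2 observed levels, found {levels}"
                )
            self.levels[name] = levels
            block = []
            # deviation coding: last level is the negative of the others
            codes = {}
            for lev in levels[:-1]:
                col = (values.astype(str) == lev).astype(float) - (
                    values.astype(str) == levels[-1]
                ).astype(float)
                block.append(len(cols))
                cols.append(col.to_numpy())
            for i, lev in enumerate(levels):
                vec = np.zeros(len(levels) - 1)
                if i < len(levels) - 1:
                    vec[i] = 1.0
                else:
                    vec[:] = -1.0
                codes[lev] = vec
            self.level_codes[name] = codes
            self.columns.extend(f"{name}[{lev}]" for lev in levels[:-1])
            self.blocks[name] = block

        for f in factors:
            add_factor(f, data[f])
        for cov in covariates:
            centred = data[cov].astype(float) - data[cov].astype(float).mean()
            self.blocks[cov] = [len(cols)]
            cols.append(centred.to_numpy())
            self.columns.append(cov)
        for fa, fb in interactions:
            block = []
            for ia in self.blocks[fa]:
                for ib in self.blocks[fb]:
                    block.append(len(cols))
                    cols.append(cols[ia] * cols[ib])
                    self.columns.append(f"{self.columns[ia]}:{self.columns[ib]}")
            self.blocks[f"{fa}:{fb}"] = block

        self.X = np.column_stack(cols)
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            from scipy import linalg as sla

            # pivoted QR: columns pivoted past the numerical rank are aliased
            _, r, piv = sla.qr(self.X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(r))
            tol = (diag.max() if diag.size else 0.0) * 1e-8
            bad = [self.columns[piv[j]] for j in np.flatnonzero(diag < tol)]
            bad += [self.columns[j] for j in piv[diag.size :]]
            raise InvalidInputError(
                f"design matrix is rank deficient (rank {rank} < {self.X.shape[1]}); "
                f"aliased columns: {sorted(bad) or 'undetermined'}"
            )


def ancova(
    data: pd.DataFrame,
    dependent: str,
    factors: Sequence[str] = ("oxtr", "avpr1a_rs3", "oprm1"),
    covariates: Sequence[str] = ("age",),
    sex_interactions: bool = False,
) -> AssociationResult:
    """Type-III ANCOVA of ``dependent`` on genotype factors plus covariates.

    All factors enter simultaneously with sum-to-zero coding, so each
    factor's F is the marginal (Type-III) test of its block given everything
    else.  ``partial_eta2 = SS_factor / (SS_factor + SS_error)`` with
    ``SS_factor = F * df_num * MSE``.  With ``sex_interactions=True`` a sex
    factor and sex × gene interaction terms are added and tested.

    Pairwise genotype contrasts (for 3-level factors) compare
    covariate-adjusted means — covariates at their grand mean, other factors
    averaged equally over levels — using the model error term, with the
    Bonferroni per-comparison threshold 0.05 / n_pairs and Cohen's
    d = difference / sqrt(MSE).
    """
    import statsmodels.api as sm

    factors = list(factors)
    interactions = []
    if sex_interactions:
        if "sex" not in data.columns:
            raise DataError("sex_interactions=True requires a 'sex' column")
        base_factors = [f for f in factors if f != "sex"]
        factors = base_factors + ["sex"]
        interactions = [("sex", f) for f in base_factors]

    derived = {"avpr1a_rs3", "carrier_334"}
    if (derived & set(factors)) - set(data.columns) and {
        "avpr1a_allele1_bp",
        "avpr1a_allele2_bp",
    } <= set(data.columns):
        data = add_derived_genotypes(data)
    needed = [dependent, *factors, *covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise DataError(f"association table is missing columns: {missing}")
    clean = data.dropna(subset=needed)

    design = _Design(clean, factors, covariates, interactions)
    y = clean[dependent].astype(float).to_numpy()
    n, k = design.X.shape
    if n <= k:
        raise InvalidInputError(f"n = {n} too small for a {k}-column model")

    model = sm.OLS(y, design.X).fit()
    df_den = int(model.df_resid)
    mse = float(model.mse_resid)
    # an exactly-fit model (e.g. constant dependent) has no error variance;
    # every marginal test is vacuous and reported as zero effect
    degenerate = float(model.ssr) <= 1e-12 * max(1.0, float((y**2).sum()))

    tests = []
    testable = [f for f in factors] + [f"{a}:{b}" for a, b in interactions]
    for name in testable:
        block = design.blocks[name]
        df_num = len(block)
        if degenerate:
            tests.append(FactorTest(name, 0.0, df_num, df_den, 1.0, 0.0))
            continue
        contrast = np.zeros((df_num, k))
        for r, j in enumerate(block):
            contrast[r, j] = 1.0
        ft = model.f_test(contrast)
        F = float(ft.fvalue)
        ss_factor = F * df_num * mse
        tests.append(
            FactorTest(
                factor=name,
                F=F,
                df_num=df_num,
                df_den=df_den,
                p=float(ft.pvalue),
                partial_eta2=ss_factor / (ss_factor + mse * df_den),
            )
        )

    contrasts = []
    for name in factors:
        if len(design.levels[name]) == 3:
            contrasts.extend(pairwise_bonferroni(model, design, name))

    return AssociationResult(
        dependent=dependent,
        n=n,
        df_den=df_den,
        mse=mse,
        factor_tests=tuple(tests),
        contrasts=tuple(contrasts),
    )


def pairwise_bonferroni(model, design: _Design, factor: str) -> list[PairwiseContrast]:
    """All pairwise adjusted-mean comparisons for one factor.

    The contrast vector between two levels touches only the factor's own
    sum-coded columns (covariates sit at the grand mean and other factors
    average out), so the difference in adjusted means is a linear function
    of the fitted coefficients; t uses the model's error covariance and the
    per-comparison threshold is 0.05 divided by the number of pairs.
    """
    levels = design.levels[factor]
    pairs = list(itertools.combinations(levels, 2))
    threshold = 0.05 / len(pairs)
    mse = float(model.mse_resid)
    degenerate = float(model.ssr) <= 1e-12
    out = []
    k = model.params.shape[0]
    for lev_a, lev_b in pairs:
        if degenerate:
            out.append(
                PairwiseContrast(
                    factor, lev_a, lev_b, 0.0, 0.0, int(model.df_resid), 1.0,
                    round(threshold, 3), 0.0,
                )
            )
            continue
        c = np.zeros(k)
        codes = design.level_codes[factor]
        for j, col in enumerate(design.blocks[factor]):
            c[col] = codes[lev_a][j] - codes[lev_b][j]
        tt = model.t_test(c)
        est = float(np.squeeze(tt.effect))
        out.append(
            PairwiseContrast(
                factor=factor,
                level_a=lev_a,
                level_b=lev_b,
                estimate=est,
                t=float(np.squeeze(tt.tvalue)),
                df=int(model.df_resid),
                p=float(np.squeeze(tt.pvalue)),
                bonferroni_threshold=round(threshold, 3),
                cohen_d=est / np.sqrt(mse),
            )
        )
    return out


def pearson_corr(u: Sequence[float], v: Sequence[float]) -> tuple[float, int, float]:
    """Product-moment correlation with its t-based p; returns (r, df, p)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise InvalidInputError("inputs must be equal-length 1-D vectors")
    if u.size < 3:
        raise InvalidInputError("need at least 3 observations")
    res = stats.pearsonr(u, v)
    return float(res.statistic), u.size - 2, float(res.pvalue)


# ---------------------------------------------------------------------------
# descriptive genotype report


def genotype_report(genotypes: pd.DataFrame) -> dict:
    """Counts, percentages, HWE tests, pairwise independence and 334 bp
    carrier rates for a genotype table (RS3 columns derived if absent)."""
    if "avpr1a_rs3" not in genotypes.columns:
        genotypes = add_derived_genotypes(genotypes)
    report: dict = {"n": int(len(genotypes)), "genes": {}, "independence": {}}
    for gene, order in GENOTYPE_COLUMNS.items():
        counts = genotype_counts(genotypes[gene], order)
        hwe = hwe_chisq(counts)
        report["genes"][gene] = {
            "order": list(order),
            "counts": list(counts),
            "percent": [round(100 * c / counts.total, 1) for c in counts],
            "hwe_chi2": hwe.chi2,
            "hwe_p": hwe.p,
        }
    for ga, gb in itertools.combinations(GENOTYPE_COLUMNS, 2):
        table = pd.crosstab(genotypes[ga], genotypes[gb]).to_numpy()
        chi2, df, p = crosstab_chisq(table)
        report["independence"][f"{ga}~{gb}"] = {"chi2": chi2, "df": df, "p": p}
    n_car = int(genotypes["carrier_334"].sum())
    report["carrier_334"] = {
        "carriers": n_car,
        "non_carriers": int(len(genotypes) - n_car),
        "percent": round(100 * n_car / len(genotypes), 1),
    }
    return report
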