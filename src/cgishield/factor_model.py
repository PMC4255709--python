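"""Logistic modelling of binary CGI methylation state from genomic factors.

The binary methylation state M of each CGI is modelled as a logistic linear
combination of binary factors — promoter association (PA), R-loop formation
potential (Rloop, G-skew of the transcribed strand), Cfp1 binding, H3K4me3
enrichment, and presence of a motif (Motif) — plus, in the
promoter-activity variant, a continuous activity predictor P (log10 of
maximum TPM) and a binding indicator with interaction.

All reported tests are likelihood-ratio (deviance-difference) tests, the
natural companion of the deviance-reduction effect-size measure; Wald
standard errors from the final IRLS weights accompany the coefficients.
Fitting is maximum likelihood by IRLS via statsmodels GLM (binomial family,
logit link).
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .io_intervals import reverse_complement

FACTORS = ("PA", "Rloop", "Cfp1", "H3K4me3", "Motif")

# coefficients (intercept, P, E2F1, P:E2F1) of the published MCF7 model of
# methylation state from promoter activity and E2F1 binding
MCF7_MODEL_COEF = (-1.31, -1.63, -3.49, 0.60)


@dataclasses.dataclass
class ModelFit:
    """A fitted logistic model: coefficients, SEs and deviances."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    deviance: float
    null_deviance: float
    converged: bool
    n: int
    separation: bool = False

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.params["Intercept"], dtype=float)
        for term in self.terms:
            if term == "Intercept":
                continue
            if ":" in term:
                a, b = term.split(":")
                eta += self.params[term] * X[a].to_numpy() * X[b].to_numpy()
            else:
                eta += self.params[term] * X[term].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def gskew_rloop_potential(sequence: str, transcript_strand: str,
                          strand_convention: str = "sense") -> int:
    """R-loop formation potential of a CGI: G-skew of the transcribed strand.

    The sequence is oriented to the strand whose 5'->3' reading matches the
    transcript (the sense strand, by default), and the factor is 1 iff that
    strand contains strictly more G than C residues. Ties give 0. With
    ``strand_convention="template"`` the opposite strand is used. N bases
    count as neither G nor C.
    """
    if transcript_strand not in ("+", "-"):
        raise ValueError("transcript strand must be known ('+' or '-')")
    if strand_convention not in ("sense", "template"):
        raise ValueError("strand_convention must be 'sense' or 'template'")
    flip = (transcript_strand == "-") ^ (strand_convention == "template")
    s = reverse_complement(sequence) if flip else sequence
    return int(s.count("G") > s.count("C"))


def _design_matrix(table: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": np.ones(len(table))}, index=table.index)
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            X[term] = table[a].to_numpy(float) * table[b].to_numpy(float)
        else:
            X[term] = table[term].to_numpy(float)
    return X


def fit_logistic(table: pd.DataFrame, terms: Sequence[str] = (),
                 outcome: str = "M") -> ModelFit:
    """Maximum-likelihood logistic fit of ``outcome`` on the given terms.

    ``terms`` are column names; ``"A:B"`` denotes an interaction (product)
    term. The intercept is always included. Rank-deficient designs raise a
    ValueError naming the collinear terms; complete separation is flagged.
    """
    y = table[outcome].to_numpy(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = _design_matrix(table, terms)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design among terms {list(X.columns)}")
    if len(table) <= X.shape[1]:
        raise ValueError("need n > number of terms")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with np.errstate(all="ignore"):
        res = model.fit(maxiter=100, tol=1e-8)
    fitted = res.fittedvalues
    separation = bool(np.any(np.abs(res.params) > 15) and
                      (np.all((fitted > 0.999) == (y == 1))))
    return ModelFit(
        terms=("Intercept", *terms),
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        converged=bool(res.converged),
        n=len(table),
        separation=separation,
    )


def likelihood_ratio_test(reduced: ModelFit, full: ModelFit, df: int = 1) -> tuple[float, float]:
    """LRT statistic (deviance difference, >= 0 for nested fits) and chi2 p."""
    stat = max(reduced.deviance - full.deviance, 0.0)
    return stat, float(stats.chi2.sf(stat, df))


def deviance_reduction(table: pd.DataFrame, factor: str,
                       outcome: str = "M") -> tuple[float, float]:
    """Deviance reduction of the single-factor model vs null, with chi2 p."""
    fit = fit_logistic(table, [factor], outcome)
    reduction = fit.null_deviance - fit.deviance
    return float(reduction), float(stats.chi2.sf(reduction, 1))


def rank_factors(table: pd.DataFrame, factors: Sequence[str] = FACTORS,
                 outcome: str = "M") -> pd.DataFrame:
    """Each factor's isolated deviance reduction, ranked descending."""
    rows = []
    for f in factors:
        red, p = deviance_reduction(table, f, outcome)
        rows.append({"factor": f, "deviance_reduction": red, "p": p})
    df = pd.DataFrame(rows).sort_values("deviance_reduction", ascending=False)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def added_value_test(table: pd.DataFrame, base_factor: str, added_factor: str,
                     outcome: str = "M") -> tuple[float, float]:
    """LRT of {base} vs {base, added}: does the added factor improve fit?"""
    reduced = fit_logistic(table, [base_factor], outcome)
    full = fit_logistic(table, [base_factor, added_factor], outcome)
    return likelihood_ratio_test(reduced, full)


def interaction_network(
    table: pd.DataFrame,
    factors: Sequence[str] = FACTORS,
    alpha: float = 0.05,
    outcome: str = "M",
) -> pd.DataFrame:
    """Pairwise interaction tests with Bonferroni correction.

    For every unordered factor pair, the main-effects model is compared with
    the model plus the product term (LRT, 1 df); Bonferroni m is the number
    of pairs tested in the run. Pairs whose interaction model is
    non-estimable (empty cells / separation) are flagged with NaN p.
    """
    if len(factors) < 2:
        raise ValueError("need at least two factors")
    pairs = list(itertools.combinations(factors, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        try:
            reduced = fit_logistic(table, [a, b], outcome)
            full = fit_logistic(table, [a, b, f"{a}:{b}"], outcome)
            stat, p = likelihood_ratio_test(reduced, full)
            if full.separation:
                stat, p = float("nan"), float("nan")
        except (ValueError, np.linalg.LinAlgError):
            stat, p = float("nan"), float("nan")
        rows.append({
            "factor_a": a, "factor_b": b,
            "deviance_reduction": stat, "p": p,
            "p_bonferroni": min(p * m, 1.0) if np.isfinite(p) else float("nan"),
            "significant": bool(np.isfinite(p) and p * m < alpha),
        })
    return pd.DataFrame(rows)


def stratified_or(
    table: pd.DataFrame,
    outcome: str,
    exposure: str,
    stratum_var: str,
) -> pd.DataFrame:
    """Per-stratum effect of a binary exposure on the outcome fraction.

    The protective odds ratio is odds(outcome | unexposed) /
    odds(outcome | exposed), so OR > 1 means the exposure protects against
    the outcome; the risk orientation (its reciprocal) is reported
    alongside, with the percentage-point reduction in the outcome fraction
    and a Fisher exact p. Zero margins give infinite/zero ORs, flagged via
    the ``degenerate`` column.
    """
    rows = []
    for stratum, sub in table.groupby(stratum_var):
        exp1 = sub[sub[exposure] == 1]
        exp0 = sub[sub[exposure] == 0]
        a = int((exp0[outcome] == 1).sum())  # unexposed, outcome
        b = int((exp0[outcome] == 0).sum())
        c = int((exp1[outcome] == 1).sum())  # exposed, outcome
        d = int((exp1[outcome] == 0).sum())
        degenerate = min(a + b, c + d) == 0 or (b * c == 0) or (a * d == 0)
        if b * c == 0:
            or_prot = float("inf") if a * d > 0 else float("nan")
        else:
            or_prot = (a * d) / (b * c)
        frac1 = c / (c + d) if (c + d) else float("nan")
        frac0 = a / (a + b) if (a + b) else float("nan")
        _, fisher_p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({
            stratum_var: stratum,
            "or_protective": or_prot,
            "or_risk": (1.0 / or_prot if or_prot > 0 else float("inf"))
                       if not np.isnan(or_prot) else float("nan"),
            "fraction_outcome_unexposed": frac0,
            "fraction_outcome_exposed": frac1,
            "reduction_pct_points": 100.0 * (frac0 - frac1),
            "fisher_p": float(fisher_p),
            "degenerate": degenerate,
        })
    return pd.DataFrame(rows)


def factor_correlations(table: pd.DataFrame,
                        columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Pearson (phi, for 0/1 columns) correlation matrix.

    Constant columns yield NaN for their pairs (correlation undefined).
    """
    cols = list(columns) if columns is not None else \
        [c for c in table.columns if c in ("M", *FACTORS) or
         pd.api.types.is_numeric_dtype(table[c])]
    if len(cols) < 2:
        raise ValueError("need at least two columns")
    return table[cols].astype(float).corr(method="pearson")


def methylation_probability(P, e2f1, coef: Sequence[float] = MCF7_MODEL_COEF) -> np.ndarray:
    """Predicted methylation probability from the activity-binding model.

    ``coef`` is (intercept, beta_P, beta_E2F1, beta_interaction); the model
    is M ~ logit^-1(b0 + bP*P + bE*E2F1 + bPE*P*E2F1).
    """
    P = np.asarray(P, dtype=float)
    e = np.asarray(e2f1, dtype=float)
    b0, bP, bE, bPE = coef
    eta = b0 + bP * P + bE * e + bPE * P * e
    return 1.0 / (1.0 + np.exp(-eta))
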