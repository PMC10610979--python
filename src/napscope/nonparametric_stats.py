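"""Nonparametric repeated-measures statistics for the condition comparison.

The study design is a complete crossing of subjects x conditions
(negative / neutral / positive news) x 12 joint angles, with one movement
index per cell. Because the indices are ordinal or non-normal, the
analysis is rank-based throughout:

* Friedman omnibus tests — across the k = 3 conditions within each angle,
  and across the k = 12 angles within each condition — with Kendall's W
  ( = chi2 / (n (k - 1)) ) as the concordance effect size;
* Wilcoxon signed-rank post hocs on the pairs of a significant omnibus,
  Bonferroni-corrected within that omnibus family, with effect size
  r = |z| / sqrt(n_effective);
* Spearman rank correlations of body weight against each per-angle index
  within each condition.

The Friedman statistic is computed without the tie-correction factor by
default, so the W = chi2 / (n (k - 1)) identity holds exactly for every
reported pair; the tie-corrected variant is available behind a flag.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, DesignError, DomainError
from .pose_topology import ANGLE_ORDER

__all__ = [
    "CONDITIONS",
    "FriedmanResult",
    "WilcoxonResult",
    "CorrelationResult",
    "StudyTable",
    "AnalysisReport",
    "friedman",
    "kendalls_w",
    "wilcoxon_signed_rank",
    "spearman",
    "bonferroni",
    "condition_comparison",
    "DEFAULT_ALPHA",
]

#: Fixed condition order used throughout reports.
CONDITIONS = ("negative", "neutral", "positive")

DEFAULT_ALPHA = 0.050

#: Exact Wilcoxon p-values are enumerated up to this many non-zero pairs.
EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float
    W: float
    n: int
    k: int


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    z: float
    p: float
    r: float
    n_effective: int
    method: str  # "exact" or "normal"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def friedman(matrix, tie_correction: bool = False) -> FriedmanResult:
    """Friedman test on an n-blocks x k-treatments matrix.

    Values are ranked within each block (ties get average ranks) and

        chi2 = 12 / (n k (k+1)) * sum_j R_j^2  -  3 n (k+1)

    with R_j the rank sums. ``tie_correction=True`` divides by the usual
    tie factor 1 - sum(t^3 - t) / (n k (k^2 - 1)). The p-value uses the
    chi-square approximation with k - 1 degrees of freedom; an all-tied
    matrix yields chi2 = 0 (not an error).
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2:
        raise DesignError("friedman expects a 2-D blocks x treatments matrix")
    n, k = a.shape
    if n < 2 or k < 2:
        raise DesignError(f"friedman needs n >= 2 blocks and k >= 2 treatments, got {a.shape}")
    if np.isnan(a).any():
        raise DesignError("friedman matrix contains missing cells")
    ranks = sps.rankdata(a, axis=1)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)  # guard tiny negative round-off on all-tied input
    if tie_correction:
        tie_sum = 0.0
        for row in a:
            _, counts = np.unique(row, return_counts=True)
            tie_sum += float(np.sum(counts**3 - counts))
        corr = 1.0 - tie_sum / (n * k * (k**2 - 1))
        chi2 = 0.0 if corr <= 0 else chi2 / corr
    df = k - 1
    p = float(sps.chi2.sf(chi2, df))
    return FriedmanResult(chi2=float(chi2), df=df, p=p, W=kendalls_w(chi2, n, k), n=n, k=k)


def kendalls_w(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance W = chi2 / (n (k - 1)), in [0, 1]."""
    if chi2 < 0:
        raise DomainError(f"chi2 must be non-negative, got {chi2}")
    if n < 1:
        raise DomainError(f"n must be a positive block count, got {n}")
    if k < 2:
        raise DomainError(f"k must be at least 2 treatments, got {k}")
    return float(chi2) / (n * (k - 1))


def _exact_wplus_tail(ranks: np.ndarray, w_plus: float) -> tuple[float, float]:
    """P(W+ >= w_plus) and P(W+ <= w_plus) by full enumeration of sign flips."""
    n = ranks.size
    signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    dist = signs @ ranks
    eps = 1e-9
    return (
        float(np.mean(dist >= w_plus - eps)),
        float(np.mean(dist <= w_plus + eps)),
    )


def wilcoxon_signed_rank(
    x, y=None, alternative: str = "two-sided", method: str = "auto"
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples (or on differences directly).

    Zero differences are dropped; tied absolute differences get average
    ranks. The p-value is exact (full 2^n enumeration of sign assignments)
    for n_effective <= 12, otherwise a normal approximation with tie
    variance correction and 0.5 continuity correction. The effect size is
    r = |z| / sqrt(n_effective); z always comes from the (continuity-
    corrected) normal standardization so that r is defined in both regimes.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")
    if method not in ("auto", "exact", "normal"):
        raise DomainError(f"unknown method {method!r}")
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    dev = w_plus - mean
    if var <= 0:
        z = 0.0
    else:
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / math.sqrt(var) if dev != 0 else 0.0
    r = abs(z) / math.sqrt(n)

    use_exact = method == "exact" or (method == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        p_ge, p_le = _exact_wplus_tail(ranks, w_plus)
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        how = "exact"
    else:
        if var <= 0:
            p = 1.0
        else:
            sd = math.sqrt(var)
            if alternative == "greater":
                p = float(sps.norm.sf((dev - 0.5) / sd))
            elif alternative == "less":
                p = float(sps.norm.cdf((dev + 0.5) / sd))
            else:
                z_cc = max(abs(dev) - 0.5, 0.0) / sd
                p = float(min(1.0, 2.0 * sps.norm.sf(z_cc)))
        how = "normal"
    return WilcoxonResult(w_plus=w_plus, z=float(z), p=float(p), r=float(r), n_effective=n, method=how)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of average ranks,
    p-value from the t approximation with n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("spearman expects two equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise DomainError(f"spearman needs at least 3 pairs, got {n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise DegenerateDataError("zero rank variance; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p=p, n=n)


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Bonferroni adjustment p_adj = min(1, m p); order preserved."""
    ps = list(p_values)
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"p-value outside [0, 1]: {p}")
    m = len(ps) if m is None else m
    return [min(1.0, m * p) for p in ps]


@dataclass
class StudyTable:
    """Long-format study data plus the per-subject body-weight covariate.

    ``data`` columns: subject, condition, angle, index, value — one value
    per (subject, condition, angle, index) cell, complete crossing required
    per index. ``body_weight`` maps subject -> weight in kg.
    """

    data: pd.DataFrame
    body_weight: dict = field(default_factory=dict)

    REQUIRED = ("subject", "condition", "angle", "index", "value")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise DesignError(f"study table missing columns: {sorted(missing)}")

    @property
    def subjects(self) -> list:
        return sorted(self.data["subject"].unique())

    @property
    def conditions(self) -> list[str]:
        present = set(self.data["condition"].unique())
        ordered = [c for c in CONDITIONS if c in present]
        return ordered + sorted(present - set(CONDITIONS))

    @property
    def angles(self) -> list[str]:
        present = set(self.data["angle"].unique())
        return [a.value for a in ANGLE_ORDER if a.value in present] + sorted(
            present - {a.value for a in ANGLE_ORDER}
        )

    @property
    def indices(self) -> list[str]:
        return sorted(self.data["index"].unique())

    def pivot(self, index_name: str, within: str, at: str):
        """Blocks x treatments matrix for one index.

        ``within="angle"``: rows = subjects, columns = conditions at angle ``at``.
        ``within="condition"``: rows = subjects, columns = angles at condition ``at``.
        """
        df = self.data[self.data["index"] == index_name]
        if within == "angle":
            df = df[df["angle"] == at]
            piv = df.pivot_table(index="subject", columns="condition", values="value", aggfunc="first")
            piv = piv.reindex(columns=self.conditions)
        elif within == "condition":
            df = df[df["condition"] == at]
            piv = df.pivot_table(index="subject", columns="angle", values="value", aggfunc="first")
            piv = piv.reindex(columns=self.angles)
        else:
            raise DomainError(f"unknown scope {within!r}")
        piv = piv.reindex(index=self.subjects)
        if piv.isna().any().any():
            raise DesignError(
                f"incomplete crossing for index {index_name!r} ({within}={at!r})"
            )
        return piv


_REPORT_COLUMNS = [
    "scope", "index", "angle", "condition", "comparison",
    "test", "statistic", "df", "n", "p", "p_adj", "significant", "effect_size",
]


@dataclass
class AnalysisReport:
    """Flat table of every test performed, plus the significance level used."""

    tests: pd.DataFrame
    alpha: float

    def to_csv(self, path) -> None:
        self.tests.to_csv(path, index=False, float_format="%.6g")

    def section(self, scope: str) -> pd.DataFrame:
        return self.tests[self.tests["scope"] == scope].reset_index(drop=True)

    def rejection_fraction(self, scope: str) -> float:
        sec = self.section(scope)
        if sec.empty:
            return float("nan")
        return float(sec["significant"].mean())

    def summary(self) -> str:
        lines = [f"Nonparametric condition comparison (alpha = {self.alpha:.3f})", ""]
        for scope, label in [
            ("angle_omnibus", "Friedman across conditions, per angle"),
            ("condition_omnibus", "Friedman across angles, per condition"),
            ("posthoc", "Wilcoxon signed-rank post hocs (Bonferroni-corrected)"),
            ("correlation", "Spearman: body weight vs index"),
        ]:
            sec = self.section(scope)
            if sec.empty:
                continue
            lines.append(label)
            for _, row in sec.iterrows():
                where = row["angle"] if scope == "angle_omnibus" else row["condition"]
                if scope == "posthoc":
                    where = f"{row['angle'] or row['condition']}: {row['comparison']}"
                if scope == "correlation":
                    where = f"{row['condition']}/{row['angle']}"
                sig = "*" if row["significant"] else " "
                eff = (
                    f", effect={row['effect_size']:.3f}"
                    if row["significant"] and pd.notna(row["effect_size"])
                    else ""
                )
                stat_name = {"friedman": "chi2", "wilcoxon": "z", "spearman": "rho"}[row["test"]]
                df_part = f"({int(row['df'])})" if pd.notna(row["df"]) else ""
                lines.append(
                    f"  [{sig}] {row['index']:<16} {str(where):<28} "
                    f"{stat_name}{df_part} = {row['statistic']:.3f}, p = {row['p']:.3f}{eff}"
                )
            lines.append("")
        return "\n".join(lines)


def _friedman_row(scope, index_name, angle, condition, res: FriedmanResult, alpha):
    sig = res.p < alpha
    return {
        "scope": scope, "index": index_name, "angle": angle, "condition": condition,
        "comparison": "", "test": "friedman", "statistic": res.chi2, "df": res.df,
        "n": res.n, "p": res.p, "p_adj": res.p, "significant": sig,
        "effect_size": res.W if sig else float("nan"),
    }


def condition_comparison(
    study: StudyTable,
    alpha: float = DEFAULT_ALPHA,
    tie_correction: bool = False,
) -> AnalysisReport:
    """Run the full nonparametric analysis design on one study.

    For every index: (a) per-angle Friedman across conditions; (b)
    per-condition Friedman across angles; (c) pairwise Wilcoxon signed-rank
    post hocs wherever an omnibus is significant, Bonferroni-corrected
    within that omnibus family (3 condition pairs, or 66 angle pairs);
    (d) Spearman correlation of body weight with each per-angle index in
    each condition. Effect sizes (W, r, rho) are attached to significant
    results only, mirroring the reporting convention of the study design.
    """
    rows: list[dict] = []
    conditions = study.conditions
    angles = study.angles

    for index_name in study.indices:
        # (a) across conditions within each angle, plus post hocs
        for angle in angles:
            piv = study.pivot(index_name, within="angle", at=angle)
            res = friedman(piv.to_numpy(), tie_correction=tie_correction)
            rows.append(_friedman_row("angle_omnibus", index_name, angle, "", res, alpha))
            if res.p < alpha:
                rows.extend(
                    _posthoc_rows(piv, "angle", index_name, angle, alpha)
                )
        # (b) across angles within each condition, plus post hocs
        for condition in conditions:
            piv = study.pivot(index_name, within="condition", at=condition)
            res = friedman(piv.to_numpy(), tie_correction=tie_correction)
            rows.append(
                _friedman_row("condition_omnibus", index_name, "", condition, res, alpha)
            )
            if res.p < alpha:
                rows.extend(
                    _posthoc_rows(piv, "condition", index_name, condition, alpha)
                )
        # (d) body weight correlations
        if study.body_weight:
            for condition in conditions:
                piv = study.pivot(index_name, within="condition", at=condition)
                weights = np.array([study.body_weight[s] for s in piv.index])
                for angle in piv.columns:
                    try:
                        cres = spearman(weights, piv[angle].to_numpy())
                    except DegenerateDataError:
                        continue
                    sig = cres.p < alpha
                    rows.append(
                        {
                            "scope": "correlation", "index": index_name, "angle": angle,
                            "condition": condition, "comparison": "body_weight",
                            "test": "spearman", "statistic": cres.rho, "df": float("nan"),
                            "n": cres.n, "p": cres.p, "p_adj": cres.p,
                            "significant": sig,
                            "effect_size": abs(cres.rho) if sig else float("nan"),
                        }
                    )
    tests = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return AnalysisReport(tests=tests, alpha=alpha)


def _posthoc_rows(piv: pd.DataFrame, within: str, index_name: str, at: str, alpha: float):
    """Pairwise Wilcoxon post hocs for one significant omnibus family."""
    pairs = list(itertools.combinations(list(piv.columns), 2))
    results, ps = [], []
    for a, b in pairs:
        try:
            w = wilcoxon_signed_rank(piv[a].to_numpy(), piv[b].to_numpy())
        except DegenerateDataError:
            w = None
        results.append((a, b, w))
        ps.append(w.p if w is not None else 1.0)
    adj = bonferroni(ps)
    rows = []
    for (a, b, w), p_adj in zip(results, adj):
        if w is None:
            continue
        sig = p_adj < alpha
        rows.append(
            {
                "scope": "posthoc", "index": index_name,
                "angle": at if within == "angle" else "",
                "condition": at if within == "condition" else "",
                "comparison": f"{a} vs {b}", "test": "wilcoxon",
                "statistic": w.z, "df": float("nan"), "n": w.n_effective,
                "p": w.p, "p_adj": p_adj, "significant": sig,
                "effect_size": w.r if sig else float("nan"),
            }
        )
    return rows
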