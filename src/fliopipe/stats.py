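"""Cohort-level statistics for regional fluorescence lifetimes.

Implements the statistical battery of the smoking/FLIO study design:

* unpaired t-tests for two-group metric comparisons (pooled variance by
  default, matching common statistics-package defaults; Welch optional);
* chi-square test of independence (no continuity correction) for sex;
* median split of the smokers by pack-year (packs per day x years smoked)
  into light (below the median) and heavy (at or above) subgroups;
* one-way ANOVA with Tukey HSD post hoc tests for three-group comparisons,
  routed to Kruskal-Wallis with Dunn pairwise tests when a Shapiro-Wilk
  screen rejects normality (a reproducible stand-in for Q-Q inspection);
* Pearson correlations with Cohen's magnitude labels
  (|r| < 0.1 negligible, [0.1, 0.3) small, [0.3, 0.5) medium, >= 0.5 large);
* between-eye agreement: paired comparison and OD-OS Pearson r per item.

No correction across regions is applied by default (none was applied in
the study design this mirrors); a Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.libqsturng import psturng
from statsmodels.stats.multitest import multipletests

from .simulate import Subject, subjects_to_frame

__all__ = [
    "StatsConfig",
    "GroupAssignment",
    "CohortTables",
    "split_by_pack_year_median",
    "compare_two_groups",
    "compare_three_groups",
    "chi_square_independence",
    "correlate",
    "cohen_label",
    "significance_stars",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

MAIN_REGIONS = ("C", "IR", "OR")
PARAMETERS = ("tau1", "tau2", "tau_m")


@dataclass(frozen=True)
class StatsConfig:
    """Options for the cohort analysis."""

    alpha: float = 0.05
    t_test: str = "pooled"  # "pooled" or "welch"
    posthoc: str = "tukey"  # "tukey" or "t" (unadjusted pairwise t)
    normality_routing: bool = True  # route to Kruskal-Wallis/Dunn on Shapiro rejection
    fdr: bool = False  # Benjamini-Hochberg across regions (off: none was applied)
    eye: str = "OD"  # eye used for the main tables


@dataclass
class GroupAssignment:
    """Three-arm grouping: G0 non-smokers, G1/G2 smokers split at the median pack-year."""

    groups: dict[str, str]  # subject id -> "G0" | "G1" | "G2"
    split_value: float  # the smokers' median pack-year

    def of(self, subject_id: str) -> str:
        return self.groups[subject_id]


@dataclass
class CohortTables:
    """Result tables of the full cohort analysis."""

    covariates_two_group: pd.DataFrame
    covariates_three_group: pd.DataFrame
    flt: pd.DataFrame
    correlations: pd.DataFrame
    inter_eye: pd.DataFrame
    assignment: GroupAssignment
    notes: list[str] = field(default_factory=list)


def significance_stars(p: float) -> str:
    """The study's legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohen_label(r: float) -> str:
    """Cohen's interpretation of a correlation magnitude (left-closed bands)."""
    a = abs(r)
    if a >= 0.5:
        return "large"
    if a >= 0.3:
        return "medium"
    if a >= 0.1:
        return "small"
    return "negligible"


def split_by_pack_year_median(subjects: list[Subject]) -> GroupAssignment:
    """Split smokers at their median pack-year.

    Smokers strictly below the median form G1, those at or above it G2;
    non-smokers are G0.  With an even number of smokers and the usual
    mid-point median this yields two equal halves.
    """
    smokers = [s for s in subjects if s.group == "smoker"]
    if len(smokers) < 2:
        raise ValueError("need at least two smokers to split by median pack-year")
    split = float(np.median([s.pack_year for s in smokers]))
    groups = {}
    for s in subjects:
        if s.group == "non_smoker":
            groups[s.id] = "G0"
        else:
            groups[s.id] = "G1" if s.pack_year < split else "G2"
    return GroupAssignment(groups=groups, split_value=split)


def compare_two_groups(values_a, values_b, scale: str = "metric", flavor: str = "pooled") -> tuple[float, float]:
    """Two-group comparison: unpaired t-test (metric) or chi-square (nominal).

    For nominal data the two arguments are the rows of a contingency table.
    Returns (statistic, p).
    """
    if scale == "nominal":
        return chi_square_independence(np.vstack([values_a, values_b]))
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    res = scipy.stats.ttest_ind(a, b, equal_var=(flavor == "pooled"))
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("cells must be non-negative with a positive total")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: a zero marginal")
    stat, p, _, _ = scipy.stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def _tukey_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Tukey HSD pairwise p-values via the studentized-range distribution.

    Uses the pooled within-group mean square and the Tukey-Kramer standard
    error for unequal group sizes; the range probability comes from the
    table-interpolated `psturng`.
    """
    labels = list(groups)
    k = len(labels)
    n_total = sum(len(v) for v in groups.values())
    df = n_total - k
    msw = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
    out = {}
    for g1, g2 in itertools.combinations(labels, 2):
        a, b = groups[g1], groups[g2]
        se = np.sqrt(msw / 2.0 * (1.0 / len(a) + 1.0 / len(b)))
        q = abs(a.mean() - b.mean()) / se if se > 0 else 0.0
        if q > 0:
            pv = np.asarray(psturng(q, k, df), dtype=float).ravel()[0]
            out[(g1, g2)] = float(np.clip(pv, 0.0, 1.0))
        else:
            out[(g1, g2)] = 1.0
    return out


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-sum pairwise test with tie correction (unadjusted p's)."""
    labels = list(groups)
    all_vals = np.concatenate([groups[g] for g in labels])
    n = len(all_vals)
    ranks = scipy.stats.rankdata(all_vals)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    i = 0
    for g in labels:
        k = len(groups[g])
        mean_ranks[g] = ranks[i:i + k].mean()
        sizes[g] = k
        i += k
    out = {}
    for g1, g2 in itertools.combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se
        out[(g1, g2)] = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return out


def compare_three_groups(
    groups: dict[str, np.ndarray],
    parametric: bool = True,
    posthoc: str = "tukey",
) -> dict:
    """Omnibus three-group comparison plus all pairwise post hoc p-values.

    Parametric: one-way between-subjects ANOVA with Tukey HSD pairwise
    tests (or unadjusted pairwise t-tests with ``posthoc='t'``).
    Non-parametric: Kruskal-Wallis omnibus with Dunn pairwise tests.
    Returns ``{"omnibus_stat", "omnibus_p", "pairwise": {(g1, g2): p}}``.
    """
    labels = [g for g in groups if len(groups[g])]
    if len(labels) < 3:
        raise ValueError("need three non-empty groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    if parametric:
        stat, p = scipy.stats.f_oneway(*arrays)
        if posthoc == "tukey":
            pairwise = _tukey_pairwise({g: a for g, a in zip(labels, arrays)})
        else:
            pairwise = {
                (g1, g2): compare_two_groups(groups[g1], groups[g2])[1]
                for g1, g2 in itertools.combinations(labels, 2)
            }
    else:
        stat, p = scipy.stats.kruskal(*arrays)
        pairwise = _dunn_pairwise({g: np.asarray(groups[g], dtype=float) for g in labels})
    return {"omnibus_stat": float(stat), "omnibus_p": float(p), "pairwise": pairwise}


def correlate(x, y) -> tuple[float, float, str]:
    """Pearson correlation with two-sided p and Cohen magnitude label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p), cohen_label(float(r))


def _is_normalish(values: np.ndarray, alpha: float) -> bool:
    v = np.asarray(values, dtype=float)
    if len(v) < 3 or np.std(v) == 0:
        return True
    return scipy.stats.shapiro(v).pvalue >= alpha


def run_full_analysis(
    regional: pd.DataFrame,
    subjects: list[Subject],
    config: StatsConfig = StatsConfig(),
) -> CohortTables:
    """Complete cohort analysis from per-subject regional summaries.

    ``regional`` is the tidy frame produced by regional reduction (or the
    regional-mode generator): columns subject, eye, channel, region,
    parameter, mean, sd, n_pixels.

    Produces (a) two- and three-group covariate comparisons, (b) per
    (channel, region, parameter) group comparisons of the lifetime values
    of the configured eye, (c) correlations of each regional lifetime with
    pack-year, years-smoked and regional retinal thickness, and (d)
    between-eye agreement (paired comparison and Pearson r) for the main
    regions.  Missing cells are skipped with a warning note.
    """
    notes: list[str] = []
    frame = subjects_to_frame(subjects).set_index("id")
    assignment = split_by_pack_year_median(subjects)
    frame["arm"] = [assignment.of(i) for i in frame.index]
    ns_ids = frame.index[frame.group == "non_smoker"]
    sm_ids = frame.index[frame.group == "smoker"]

    # --- (a) covariates -------------------------------------------------
    cov_rows, cov3_rows = [], []
    metric_covs = ["age", "bmi", "iop_od", "iop_os", "pack_year", "years_smoked"]
    for cov in metric_covs:
        a, b = frame.loc[ns_ids, cov].values, frame.loc[sm_ids, cov].values
        two_p = np.nan
        if cov not in ("pack_year", "years_smoked"):  # zero-variance in non-smokers
            _, two_p = compare_two_groups(a, b, flavor=config.t_test)
        cov_rows.append(dict(
            covariate=cov,
            nonsmoker_mean=a.mean(), nonsmoker_sd=a.std(ddof=1),
            nonsmoker_median=np.median(a),
            smoker_mean=b.mean(), smoker_sd=b.std(ddof=1),
            smoker_median=np.median(b),
            p=two_p, stars=significance_stars(two_p),
        ))
        arms = {g: frame.loc[frame.arm == g, cov].values for g in ("G0", "G1", "G2")}
        if cov in ("pack_year", "years_smoked"):
            arms = {g: v for g, v in arms.items() if g != "G0"}
            omni = dict(omnibus_p=np.nan, pairwise={})
            if all(len(v) >= 2 for v in arms.values()):
                _, p12 = compare_two_groups(arms["G1"], arms["G2"], flavor=config.t_test)
                omni["pairwise"] = {("G1", "G2"): p12}
        else:
            parametric = all(_is_normalish(v, config.alpha) for v in arms.values()) \
                if config.normality_routing else True
            try:
                omni = compare_three_groups(arms, parametric=parametric, posthoc=config.posthoc)
            except ValueError as e:
                omni = dict(omnibus_p=np.nan, pairwise={})
                notes.append(f"covariate {cov}: three-group comparison skipped ({e})")
        cov3_rows.append(dict(
            covariate=cov,
            G0_mean=np.mean(arms["G0"]) if "G0" in arms else np.nan,
            G1_mean=np.mean(arms["G1"]), G2_mean=np.mean(arms["G2"]),
            omnibus_p=omni.get("omnibus_p", np.nan),
            p_G0_vs_G1=omni["pairwise"].get(("G0", "G1"), np.nan),
            p_G0_vs_G2=omni["pairwise"].get(("G0", "G2"), np.nan),
            p_G1_vs_G2=omni["pairwise"].get(("G1", "G2"), np.nan),
        ))
    # Sex: chi-square on the 2x2 sex-by-group table.
    sex_table = np.array([
        [(frame.loc[ids, "sex"] == "M").sum(), (frame.loc[ids, "sex"] == "F").sum()]
        for ids in (ns_ids, sm_ids)
    ])
    try:
        _, sex_p = chi_square_independence(sex_table)
    except ValueError:
        sex_p = np.nan
        notes.append("sex table degenerate; chi-square skipped")
    cov_rows.append(dict(
        covariate="sex_male", nonsmoker_mean=sex_table[0, 0], nonsmoker_sd=np.nan,
        nonsmoker_median=np.nan, smoker_mean=sex_table[1, 0], smoker_sd=np.nan,
        smoker_median=np.nan, p=sex_p, stars=significance_stars(sex_p),
    ))

    # --- (b,c) regional lifetimes --------------------------------------
    eye_df = regional[regional.eye == config.eye]
    pivot = eye_df.pivot_table(index="subject", columns=["channel", "region", "parameter"],
                               values="mean")
    flt_rows, corr_rows = [], []
    for (channel, region, parameter) in sorted(pivot.columns):
        col = pivot[(channel, region, parameter)]
        if col.isna().any():
            missing = col.index[col.isna()].tolist()
            notes.append(f"{channel}/{region}/{parameter}: missing subjects {missing}; skipped")
            logger.warning("missing cells for %s/%s/%s", channel, region, parameter)
            continue
        a = col.loc[[i for i in ns_ids if i in col.index]].values
        b = col.loc[[i for i in sm_ids if i in col.index]].values
        _, two_p = compare_two_groups(a, b, flavor=config.t_test)
        arms = {g: col.loc[[i for i in frame.index[frame.arm == g] if i in col.index]].values
                for g in ("G0", "G1", "G2")}
        parametric = all(_is_normalish(v, config.alpha) for v in arms.values()) \
            if config.normality_routing else True
        if not parametric:
            notes.append(f"{channel}/{region}/{parameter}: routed to Kruskal-Wallis/Dunn")
        try:
            omni = compare_three_groups(arms, parametric=parametric, posthoc=config.posthoc)
        except ValueError as e:
            omni = dict(omnibus_stat=np.nan, omnibus_p=np.nan, pairwise={})
            notes.append(f"{channel}/{region}/{parameter}: three-group comparison skipped ({e})")
        flt_rows.append(dict(
            channel=channel, region=region, parameter=parameter,
            nonsmoker_mean=a.mean(), nonsmoker_sd=a.std(ddof=1),
            smoker_mean=b.mean(), smoker_sd=b.std(ddof=1),
            G0_mean=arms["G0"].mean(), G1_mean=arms["G1"].mean(), G2_mean=arms["G2"].mean(),
            G0_sd=arms["G0"].std(ddof=1), G1_sd=arms["G1"].std(ddof=1), G2_sd=arms["G2"].std(ddof=1),
            p_two_group=two_p, stars_two_group=significance_stars(two_p),
            omnibus_p=omni["omnibus_p"],
            p_G0_vs_G1=omni["pairwise"].get(("G0", "G1"), np.nan),
            p_G0_vs_G2=omni["pairwise"].get(("G0", "G2"), np.nan),
            p_G1_vs_G2=omni["pairwise"].get(("G1", "G2"), np.nan),
            parametric=parametric,
        ))
        vals = col.loc[frame.index.intersection(col.index)]
        for target, x in (
            ("pack_year", frame.loc[vals.index, "pack_year"].values),
            ("years_smoked", frame.loc[vals.index, "years_smoked"].values),
            ("thickness", frame.loc[vals.index, f"thickness_{region}"].values
             if f"thickness_{region}" in frame else None),
        ):
            if x is None or np.std(x) == 0 or np.any(~np.isfinite(x)):
                continue
            r, p, label = correlate(x, vals.values)
            corr_rows.append(dict(channel=channel, region=region, parameter=parameter,
                                  against=target, r=r, p=p, cohen=label,
                                  stars=significance_stars(p)))

    flt = pd.DataFrame(flt_rows)
    if config.fdr and len(flt):
        flt["p_two_group_fdr"] = multipletests(flt["p_two_group"], method="fdr_bh")[1]

    # --- (d) between-eye agreement -------------------------------------
    both = regional.pivot_table(index="subject", columns=["eye", "channel", "region", "parameter"],
                                values="mean")
    inter_rows = []
    for channel in sorted(regional.channel.unique()):
        for region in MAIN_REGIONS:
            for parameter in PARAMETERS:
                try:
                    od = both[("OD", channel, region, parameter)]
                    os_ = both[("OS", channel, region, parameter)]
                except KeyError:
                    continue
                mask = od.notna() & os_.notna()
                if mask.sum() < 3:
                    continue
                x, y = od[mask].values, os_[mask].values
                if np.allclose(x, y):
                    r, rp, label = 1.0, 0.0, "large"
                    paired_p = 1.0
                else:
                    r, rp, label = correlate(x, y)
                    paired_p = float(scipy.stats.ttest_rel(x, y).pvalue)
                inter_rows.append(dict(channel=channel, region=region, parameter=parameter,
                                       r=r, r_p=rp, cohen=label, paired_p=paired_p,
                                       n=int(mask.sum())))

    return CohortTables(
        covariates_two_group=pd.DataFrame(cov_rows),
        covariates_three_group=pd.DataFrame(cov3_rows),
        flt=flt,
        correlations=pd.DataFrame(corr_rows),
        inter_eye=pd.DataFrame(inter_rows),
        assignment=assignment,
        notes=notes,
    )
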