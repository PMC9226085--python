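"""Group statistics and the integration of editing with circRNA results.

The statistical decision tree mirrors common clinical-cohort practice:
samples are first tested for normality; normal data get Student's t (two
groups) or one-way ANOVA with Tukey's post-hoc (more); non-normal data get
Mann-Whitney U (unpaired), Wilcoxon signed-rank (paired) or Kruskal-Wallis
(more than two groups).  Correlations switch between Pearson and Spearman
the same way.  P < 0.05 is called significant; no multiple-testing
correction is applied by default (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


def _normal(x: np.ndarray, alpha: float = ALPHA, method: str = "shapiro") -> bool:
    """Normality gate. Shapiro-Wilk by default (valid from n=3);
    D'Agostino-Pearson available for larger samples."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 3:
        return False  # constant/near-constant: cannot be called normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "dagostino":
            p = sps.normaltest(x).pvalue
        else:
            p = sps.shapiro(x).pvalue
    return bool(p >= alpha)


def choose_test(
    groups: Sequence[np.ndarray],
    paired: bool = False,
    normality: str = "shapiro",
) -> str:
    """Name of the test the decision tree selects for these samples.

    Groups with fewer than 3 values skip the normality test and default to
    the nonparametric branch (with a warning).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        warnings.warn("group size < 3: skipping normality test, using nonparametric test")
        normal = False
    else:
        normal = all(_normal(g, method=normality) for g in groups)
    if len(groups) > 2:
        return "anova_tukey" if normal else "kruskal"
    if normal:
        return "paired_t" if paired else "student_t"
    return "wilcoxon" if paired else "mannwhitney"


def run_group_test(
    groups: Sequence[np.ndarray],
    paired: bool = False,
    normality: str = "shapiro",
) -> tuple[str, float]:
    """Run the selected test; returns ``(test_name, p_value)``.

    Degenerate inputs (empty groups, all values identical) yield p = NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        return "none", float("nan")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return "none", float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        name = choose_test(groups, paired=paired, normality=normality)
        if name == "student_t":
            p = sps.ttest_ind(groups[0], groups[1], equal_var=True).pvalue
        elif name == "paired_t":
            p = sps.ttest_rel(groups[0], groups[1]).pvalue
        elif name == "mannwhitney":
            p = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue
        elif name == "wilcoxon":
            p = sps.wilcoxon(groups[0], groups[1]).pvalue
        elif name == "anova_tukey":
            p = sps.f_oneway(*groups).pvalue
        else:
            p = sps.kruskal(*groups).pvalue
    return name, float(p)


def tukey_posthoc(groups: Sequence[np.ndarray], labels: Sequence[str]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (companion to the ANOVA branch)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    grp = np.concatenate([[lab] * len(g) for g, lab in zip(groups, labels)])
    res = pairwise_tukeyhsd(values, grp, alpha=ALPHA)
    return pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])


# ---------------------------------------------------------------------------
# differential circRNA analysis
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    feature_id: str
    mean_control: float
    mean_case: float
    fold_change: float
    test: str
    p_value: float
    significant: bool
    direction: str  # up | down
    fold_change_undefined: bool = False


def differential(
    values: pd.DataFrame,
    groups: dict[str, str],
    control: str = "control",
    case: str = "HF",
    alpha: float = ALPHA,
    bh_correct: bool = False,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature two-group comparison (volcano-ready table).

    ``values`` is features x samples.  Features that are zero in every
    sample are excluded.  Fold change is case mean over control mean; a
    zero control mean with nonzero case mean is reported as +inf and
    flagged.  P < alpha marks significance (two-sided, uncorrected by
    default; set ``bh_correct`` for Benjamini-Hochberg on the q scale).
    """
    ctl_cols = [s for s in values.columns if groups.get(s) == control]
    case_cols = [s for s in values.columns if groups.get(s) == case]
    rows = []
    for fid, row in values.iterrows():
        a = row[ctl_cols].to_numpy(dtype=float)
        b = row[case_cols].to_numpy(dtype=float)
        if np.all(a == 0) and np.all(b == 0):
            continue
        test, p = run_group_test([a, b], paired=paired)
        ma, mb = float(a.mean()), float(b.mean())
        undefined = ma == 0
        fc = float("inf") if undefined else mb / ma
        rows.append(
            DifferentialResult(
                feature_id=str(fid),
                mean_control=ma,
                mean_case=mb,
                fold_change=fc,
                test=test,
                p_value=p,
                significant=False,
                direction="up" if mb >= ma else "down",
                fold_change_undefined=undefined,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature_id") if rows else pd.DataFrame(
        columns=[
            "mean_control", "mean_case", "fold_change", "test", "p_value",
            "significant", "direction", "fold_change_undefined",
        ]
    )
    if len(df):
        pvals = df["p_value"].to_numpy()
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            finite = np.isfinite(pvals)
            adj = np.full(len(pvals), np.nan)
            if finite.any():
                adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
            df["q_value"] = adj
            df["significant"] = (df["q_value"] < alpha).fillna(False)
        else:
            df["significant"] = pd.Series(pvals < alpha, index=df.index).fillna(False)
    return df


def differential_circ(bss_counts: pd.DataFrame, groups: dict[str, str], **kw) -> pd.DataFrame:
    """Differential back-splice-read analysis (features = circRNAs)."""
    return differential(bss_counts, groups, **kw)


def host_independence(
    circ_results: pd.DataFrame,
    host_results: pd.DataFrame,
    circ_host: dict[str, str],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Classify each circRNA as host_coupled or host_independent.

    host_independent: the circRNA changes significantly while its host
    mRNA does not (p >= alpha).  CircRNAs without an annotated host are
    unclassified.
    """
    rows = []
    for fid in circ_results.index:
        host = circ_host.get(str(fid))
        if host is None or host not in host_results.index:
            cls = "unclassified"
        elif not bool(circ_results.loc[fid, "significant"]):
            cls = "not_regulated"
        elif bool(host_results.loc[host, "significant"]):
            cls = "host_coupled"
        else:
            cls = "host_independent"
        rows.append({"feature_id": str(fid), "host_gene": host or "", "classification": cls})
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# flanking-intron editing overlap
# ---------------------------------------------------------------------------

def overlap_editing_flanks(
    junctions,
    sites_by_sample: dict[str, Sequence],
    annotation,
    groups: dict[str, str],
    control: str = "control",
    case: str = "HF",
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Editing events in the introns flanking each regulated BSS.

    Returns ``(per_sample, comparison)``: per-(circ, sample) counts of
    editing sites in the upstream and downstream flanking intron (half-open
    intervals; a site exactly at an intron end coordinate is outside), plus
    a per-circ group comparison of the joint counts and of each flank.  A
    flank missing because the breakpoint sits at a terminal exon is
    reported as NaN and excluded from the split view.
    """
    from circedit.annotation import AnnotationError

    rows = []
    for j in junctions:
        try:
            up, down = annotation.flanking_introns(j)
        except AnnotationError:
            continue  # breakpoints off exon boundaries: no flanks to score
        cid = f"{j.chrom}:{j.acceptor_pos}-{j.donor_pos}({j.strand})"
        for sample_id, sites in sites_by_sample.items():
            n_up = (
                sum(1 for s in sites if up is not None and up.contains(s.chrom, s.pos))
                if up is not None
                else np.nan
            )
            n_down = (
                sum(1 for s in sites if down is not None and down.contains(s.chrom, s.pos))
                if down is not None
                else np.nan
            )
            joint = (0 if up is None else n_up) + (0 if down is None else n_down)
            rows.append(
                {
                    "circ_id": cid,
                    "sample_id": sample_id,
                    "group": groups[sample_id],
                    "upstream": n_up,
                    "downstream": n_down,
                    "joint": joint,
                }
            )
    per_sample = pd.DataFrame(rows)
    comps = []
    group_names = [control, case]
    for cid, sub in per_sample.groupby("circ_id"):
        for flank in ("joint", "upstream", "downstream"):
            vals = [
                sub.loc[sub["group"] == g, flank].dropna().to_numpy(dtype=float)
                for g in group_names
            ]
            if any(len(v) == 0 for v in vals):
                continue
            test, p = run_group_test(vals)
            means = {g: float(v.mean()) for g, v in zip(group_names, vals)}
            direction = "down" if means[case] < means[control] else "up"
            comps.append(
                {
                    "circ_id": cid,
                    "flank": flank,
                    **{f"mean_{g}": means[g] for g in group_names},
                    "direction": direction,
                    "test": test,
                    "p_value": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    return per_sample, pd.DataFrame(comps)


# ---------------------------------------------------------------------------
# Alu pair orientation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AluPairCount:
    circ_id: str
    n_convergent: int
    n_divergent: int
    n_same_orientation: int

    @property
    def n_inverted(self) -> int:
        return self.n_convergent + self.n_divergent


def alu_pair_orientation(junction, annotation) -> AluPairCount:
    """Count Alu pairs across the two flanking introns by orientation.

    For every (upstream-intron Alu, downstream-intron Alu) pair, in genomic
    coordinates: convergent when the upstream element is on + and the
    downstream on - (arrows facing), divergent for -/+, same-orientation
    for equal strands.  Convergent plus divergent pairs are the inverted,
    circularization-competent configurations.  A missing flank or an
    Alu-free intron yields all-zero counts.
    """
    up, down = annotation.flanking_introns(junction)
    cid = f"{junction.chrom}:{junction.acceptor_pos}-{junction.donor_pos}({junction.strand})"

    def alus_in(iv):
        if iv is None:
            return []
        return [
            el
            for el in annotation.repeats
            if el.is_alu and el.interval.overlaps(iv)
        ]

    conv = div = same = 0
    for a in alus_in(up):
        for b in alus_in(down):
            sa, sb = a.interval.strand, b.interval.strand
            if sa == sb:
                same += 1
            elif sa == "+" and sb == "-":
                conv += 1
            elif sa == "-" and sb == "+":
                div += 1
    return AluPairCount(cid, conv, div, same)


# ---------------------------------------------------------------------------
# correlation & expression units
# ---------------------------------------------------------------------------

def correlate(x, y, min_n: int = 5, normality: str = "shapiro") -> tuple[str, float, float]:
    """Pearson when both vectors pass normality, else Spearman.

    Returns ``(method, coefficient, p)``.  Fewer than ``min_n`` pairs or a
    constant vector is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: correlation undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if _normal(x, method=normality) and _normal(y, method=normality):
            r, p = sps.pearsonr(x, y)
            return "pearson", float(r), float(p)
        r, p = sps.spearmanr(x, y)
    return "spearman", float(r), float(p)


def correlate_circ_host(circ_counts, host_fpkm, **kw) -> tuple[str, float, float]:
    """Correlation of circRNA BSS-spanning reads with host-gene FPKM."""
    return correlate(circ_counts, host_fpkm, **kw)


def fpkm(count: float, length_bp: float, mapped_total: float) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped total must be positive")
    return count / ((length_bp / 1e3) * (mapped_total / 1e6))


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_volcano(results: pd.DataFrame, path, alpha: float = ALPHA):
    """Volcano plot (log2 fold change vs -log10 p) with the alpha line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.replace([np.inf, -np.inf], np.nan).dropna(subset=["fold_change", "p_value"])
    fig, ax = plt.subplots(figsize=(5, 4))
    x = np.log2(df["fold_change"].clip(lower=1e-9))
    y = -np.log10(df["p_value"].clip(lower=1e-300))
    sig = df["significant"].astype(bool)
    ax.scatter(x[~sig], y[~sig], s=12, c="grey", label="n.s.")
    ax.scatter(x[sig], y[sig], s=14, c="crimson", label=f"p < {alpha}")
    ax.axhline(-np.log10(alpha), ls="--", c="black", lw=0.8)
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 p")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
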