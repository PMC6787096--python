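"""Interaction scoring: from raw construct counts to anchor-synergy calls.

The chain is the screen's analysis recipe:

1. **Background correction** — per sample, subtract the median count of the
   control-control constructs (pure sequencing/background signal), floor at
   zero, and drop the control-control rows.
2. **Abundance filter** — drop constructs without >= ``min_cpm`` counts per
   million in >= ``min_samples`` samples.
3. **TMM normalization** — trimmed-mean-of-M-values scale factors so that
   differential abundance is not distorted by composition bias.
4. **Differential abundance** — per construct, a negative-binomial exact
   test of T14 vs T0 with a common (Cox-Reid adjusted) dispersion, log2
   fold changes (depletion at T14 negative) and Benjamini-Hochberg FDR.
5. **Interaction calling** — gene-level mean phenotypes for the
   control-target (single-knockout) and anchor-target (double-knockout)
   arms, subtraction of the anchor-alone phenotype from the double arm, and
   a call when the single/adjusted-double ratio falls below the threshold
   (the adjusted double effect more than 1/threshold times the single
   effect).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from statsmodels.stats.multitest import multipletests

from .library import CONTROL, Category, DualConstruct

# ---------------------------------------------------------------------------
# Background correction and abundance filtering
# ---------------------------------------------------------------------------


def background_correct(
    counts: pd.DataFrame, categories: Mapping[str, Category | str]
) -> pd.DataFrame:
    """Subtract each sample's median control-control count; drop those rows.

    Results are floored at zero (a count cannot go negative).
    """
    ctrl_rows = [
        cid
        for cid in counts.index
        if Category(categories[cid]) is Category.CTRL_CTRL
    ]
    if not ctrl_rows:
        raise ValueError("no control-control constructs present; cannot estimate background")
    medians = counts.loc[ctrl_rows].median(axis=0)
    corrected = counts.sub(medians, axis=1).clip(lower=0)
    corrected = corrected.drop(index=ctrl_rows)
    return corrected.round().astype(int)


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 5.0, min_samples: int = 2
) -> tuple[pd.DataFrame, pd.Index]:
    """Keep constructs with CPM >= ``min_cpm`` in >= ``min_samples`` samples.

    Returns the filtered matrix and the index of removed constructs.
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples ({min_samples}) exceeds the number of samples ({counts.shape[1]})"
        )
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total count")
    cpm = counts * 1e6 / totals
    keep = (cpm >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep], counts.index[~keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
    weighted: bool,
) -> float:
    """TMM factor of one column against the reference column (log2 scale)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    finite = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a = m[finite], a[finite]
    obs_f, ref_f = obs[finite], ref[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(m)
    rank_a = sps.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    if weighted:
        w = (n_obs - obs_f) / (n_obs * obs_f) + (n_ref - ref_f) / (n_ref * ref_f)
        return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return float(np.mean(m[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    reference_column: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    Per column, log ratios (M) and average log abundances (A) against the
    reference column are double-trimmed (default 30% on M, 5% on A) and the
    surviving M values averaged with precision weights.  Rows with a zero
    count in either column of a pair are excluded for that pair.  The
    reference defaults to the column whose 75th CPM percentile is closest
    to the mean of those percentiles.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"columns with zero total count: {bad}")
    if reference_column is None:
        q75 = np.array([np.quantile(mat[:, j][mat[:, j] >= 0] / lib[j], 0.75) for j in range(mat.shape[1])])
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference_column)
    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_idx:
            continue
        pair = (mat[:, j] > 0) & (mat[:, ref_idx] > 0)
        log_factors[j] = _tmm_pair(
            mat[pair, j], mat[pair, ref_idx], lib[j], lib[ref_idx],
            logratio_trim, sum_trim, a_cutoff, weighted,
        )
    factors = np.power(2.0, log_factors)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# Differential abundance (negative binomial exact test)
# ---------------------------------------------------------------------------


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Row sums of the NB log likelihood (size r = 1/alpha)."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-12)
    ll = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def estimate_common_dispersion(
    counts: pd.DataFrame,
    lib_sizes: np.ndarray,
    groups: Sequence[np.ndarray],
    bounds: tuple[float, float] = (1e-6, 5.0),
) -> float:
    """Common NB dispersion by Cox-Reid adjusted profile likelihood.

    Group mean proportions are profiled out by their quasi-likelihood
    estimates; the adjustment subtracts half the log determinant of the
    per-construct information, which removes most of the downward bias of
    plain ML with few replicates.
    """
    y = counts.to_numpy(dtype=float)
    n = lib_sizes

    def neg_apl(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        total = 0.0
        for cols in groups:
            yg = y[:, cols]
            ng = n[cols]
            p = yg.sum(axis=1) / ng.sum()
            mu = np.outer(p, ng)
            ll = _nb_loglik(yg, mu, alpha)
            info = (mu / (1.0 + alpha * mu)).sum(axis=1)
            adj = 0.5 * np.log(np.maximum(info, 1e-12))
            nonzero = yg.sum(axis=1) > 0
            total += float((ll[nonzero] - adj[nonzero]).sum())
        return -total

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    return float(np.exp(res.x))


def estimate_trended_dispersion(
    counts: pd.DataFrame,
    lib_sizes: np.ndarray,
    groups: Sequence[np.ndarray],
    n_bins: int = 10,
    min_bin_size: int = 50,
) -> np.ndarray:
    """Abundance-dependent dispersion: the common estimate per abundance bin.

    Constructs are binned by mean scaled count (quantile bins) and a
    Cox-Reid common dispersion estimated within each bin.  Captures the
    inflated variance of low-abundance rows, e.g. after a background
    subtraction has distorted the mean-variance relation near zero.
    """
    y = counts.to_numpy(dtype=float)
    n_star = float(np.exp(np.mean(np.log(lib_sizes))))
    abundance = (y * (n_star / lib_sizes)[None, :]).mean(axis=1)
    order = np.log1p(abundance)
    n_bins = max(1, min(n_bins, len(counts) // max(min_bin_size, 1) or 1))
    try:
        bins = pd.qcut(order, n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = np.zeros(len(counts), dtype=int)
    bins = np.asarray(bins)
    alphas = np.empty(len(counts))
    for b in np.unique(bins):
        mask = bins == b
        alphas[mask] = estimate_common_dispersion(counts.loc[mask], lib_sizes, groups)
    return alphas


def _apl_profile(
    y: np.ndarray, lib_sizes: np.ndarray, groups: Sequence[np.ndarray], grid: np.ndarray
) -> np.ndarray:
    """Per-construct Cox-Reid adjusted profile log likelihood on a dispersion grid."""
    out = np.zeros((y.shape[0], grid.size))
    for gi, alpha in enumerate(grid):
        for cols in groups:
            yg = y[:, cols]
            ng = lib_sizes[cols]
            p = yg.sum(axis=1) / ng.sum()
            mu = np.outer(p, ng)
            info = (mu / (1.0 + alpha * mu)).sum(axis=1)
            out[:, gi] += _nb_loglik(yg, mu, alpha) - 0.5 * np.log(np.maximum(info, 1e-12))
    return out


def estimate_tagwise_dispersion(
    counts: pd.DataFrame,
    lib_sizes: np.ndarray,
    groups: Sequence[np.ndarray],
    n_bins: int = 10,
    min_bin_size: int = 50,
    prior_df: float = 10.0,
    grid: np.ndarray | None = None,
) -> np.ndarray:
    """Per-construct dispersion shrunk toward the abundance trend.

    Empirical-Bayes estimate in the style of edgeR's default pipeline: each
    construct's Cox-Reid adjusted profile likelihood is combined with the
    mean profile of its abundance bin, weighted ``prior_df`` prior degrees
    of freedom against the construct's own residual df, and maximized on a
    log-spaced grid.  Constructs whose replicates genuinely disagree keep a
    large dispersion (and stay non-significant) without dragging their
    whole abundance bin with them.
    """
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(20.0), 40))
    y = counts.to_numpy(dtype=float)
    n_star = float(np.exp(np.mean(np.log(lib_sizes))))
    abundance = np.log1p((y * (n_star / lib_sizes)[None, :]).mean(axis=1))
    n_bins = max(1, min(n_bins, len(counts) // max(min_bin_size, 1) or 1))
    try:
        bins = np.asarray(pd.qcut(abundance, n_bins, labels=False, duplicates="drop"))
    except ValueError:
        bins = np.zeros(len(counts), dtype=int)
    apl = _apl_profile(y, lib_sizes, groups, grid)
    resid_df = max(1, y.shape[1] - len(groups))
    weight = prior_df / resid_df
    score = apl.copy()
    for b in np.unique(bins):
        mask = bins == b
        score[mask] += weight * apl[mask].mean(axis=0)[None, :]
    return grid[np.argmax(score, axis=1)]


def _exact_nb_pvalue(s1: float, s2: float, n1: int, n2: int, alpha: float) -> float:
    """Two-sided exact NB test of equal means given group sums of pseudo-counts.

    ``s1``/``s2`` are sums of ``n1``/``n2`` replicate counts at a common
    library size.  Conditions on the total and sums the probability of all
    outcomes no more likely than the observed split.
    """
    t = int(round(s1 + s2))
    if t == 0:
        return 1.0
    lam = t / (n1 + n2)
    mu1, mu2 = n1 * lam, n2 * lam
    if alpha <= 1e-10:
        # Poisson limit: conditional distribution is binomial
        k = np.arange(t + 1)
        logp = sps.binom.logpmf(k, t, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / alpha, n2 / alpha
        k = np.arange(t + 1)
        p1 = r1 / (r1 + mu1)
        p2 = r2 / (r2 + mu2)
        logp = sps.nbinom.logpmf(k, r1, p1) + sps.nbinom.logpmf(t - k, r2, p2)
        logp = logp - special.logsumexp(logp)
    obs = int(round(s1))
    obs = min(max(obs, 0), t)
    keep = logp <= logp[obs] + 1e-10
    return float(min(1.0, np.exp(special.logsumexp(logp[keep]))))


@dataclass
class DifferentialResult:
    """Per-construct differential abundance of T14 relative to T0."""

    table: pd.DataFrame  # columns: logFC, pvalue, fdr, significant
    dispersion: float

    def __getitem__(self, col: str) -> pd.Series:
        return self.table[col]


def differential_abundance(
    counts: pd.DataFrame,
    factors: pd.Series,
    t0_samples: Sequence[str],
    t14_samples: Sequence[str],
    dispersion: float | str | None = None,
    pseudocount: float = 0.5,
    fdr_threshold: float = 0.1,
    max_exact_total: int = 200_000,
) -> DifferentialResult:
    """NB exact test of T14 vs T0 with TMM-scaled library sizes.

    logFC is log2 of mean T14 CPM over mean T0 CPM with a ``pseudocount``
    prior; depletion at T14 is negative.  ``dispersion=None`` estimates a
    common Cox-Reid adjusted dispersion from the data; ``"trended"``
    estimates it per abundance bin (recommended on background-corrected
    matrices, whose low-abundance rows are extra-dispersed); a float fixes
    it.  For totals above ``max_exact_total`` the conditional tail is
    evaluated by a normal approximation.
    """
    if not t0_samples or not t14_samples:
        raise ValueError("need at least one sample per timepoint")
    cols = list(t0_samples) + list(t14_samples)
    sub = counts[cols]
    lib = sub.sum(axis=0).to_numpy(dtype=float) * factors[cols].to_numpy(dtype=float)
    if (sub.sum(axis=0) <= 0).any():
        raise ValueError("a sample has zero total count")
    idx0 = np.arange(len(t0_samples))
    idx14 = np.arange(len(t0_samples), len(cols))

    if dispersion is None:
        alphas = np.full(len(sub), estimate_common_dispersion(sub, lib, [idx0, idx14]))
    elif isinstance(dispersion, str):
        if dispersion == "trended":
            alphas = estimate_trended_dispersion(sub, lib, [idx0, idx14])
        elif dispersion == "tagwise":
            alphas = estimate_tagwise_dispersion(sub, lib, [idx0, idx14])
        else:
            raise ValueError(f"unknown dispersion mode {dispersion!r}")
    else:
        alphas = np.full(len(sub), float(dispersion))

    y = sub.to_numpy(dtype=float)
    n_star = float(np.exp(np.mean(np.log(lib))))
    pseudo = y * (n_star / lib)[None, :]

    # logFC with pseudocount prior at the common library size
    mean0 = pseudo[:, idx0].mean(axis=1)
    mean14 = pseudo[:, idx14].mean(axis=1)
    logfc = np.log2(mean14 + pseudocount) - np.log2(mean0 + pseudocount)

    n1, n2 = len(idx0), len(idx14)
    s1 = pseudo[:, idx0].sum(axis=1)
    s2 = pseudo[:, idx14].sum(axis=1)
    pvals = np.ones(len(sub))
    for i in range(len(sub)):
        t = s1[i] + s2[i]
        if t <= 0:
            continue
        alpha_i = float(alphas[i])
        if t > max_exact_total:
            # normal approximation to the conditional null of the T0 share
            lam = t / (n1 + n2)
            var1 = n1 * (lam + alpha_i * lam**2)
            var2 = n2 * (lam + alpha_i * lam**2)
            sd = np.sqrt(var1 * var2 / (var1 + var2))
            z = (s1[i] - n1 * lam) / max(sd, 1e-9)
            pvals[i] = float(2 * sps.norm.sf(abs(z)))
        else:
            pvals[i] = _exact_nb_pvalue(s1[i], s2[i], n1, n2, alpha_i)
    pvals = np.clip(pvals, 0.0, 1.0)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": fdr < fdr_threshold,
            "dispersion": alphas,
        },
        index=sub.index,
    )
    return DifferentialResult(table=table, dispersion=float(np.median(alphas)))


# ---------------------------------------------------------------------------
# Gene-level aggregation and interaction calls
# ---------------------------------------------------------------------------


class CallStatus(str, enum.Enum):
    CALLED = "CALLED"
    NOT_CALLED = "NOT_CALLED"
    UNDEFINED = "UNDEFINED"          # adjusted double phenotype not a depletion
    NOT_SIGNIFICANT = "NOT_SIGNIFICANT"  # no double-arm construct passed the FDR gate


def call_interactions(
    diff: DifferentialResult | pd.DataFrame,
    library: Sequence[DualConstruct] | pd.DataFrame,
    anchor: str,
    ratio_threshold: float = 0.5,
    fdr_threshold: float = 0.1,
    adjust: str = "subtract",
    min_double_effect: float = 0.1,
    min_sig_constructs: int = 2,
    require_single_depletion: bool = False,
    gate: str = "gene",
) -> pd.DataFrame:
    """Call genes whose double-knockout phenotype exceeds the single effects.

    Per gene g, mean logFC phenotypes are computed for the control-g
    (single-knockout) arm, the anchor-g (double-knockout) arm, and the
    anchor-control arm (``P_anchor``, a nuisance estimate that is never
    FDR-gated).  The anchor effect is removed additively in log space
    (``P_double_adj = P_double_raw - P_anchor``; ``adjust="divide"``
    rescales instead).  The ratio ``r = P_single / P_double_adj`` is formed
    only when the adjusted double phenotype is a depletion
    (``P_double_adj < -min_double_effect``); genes are CALLED when
    ``r < ratio_threshold``.

    The FDR gate selecting which genes show a real double-knockout
    phenotype is applied per ``gate``:

    ``"gene"`` (default)
        Construct p-values of each gene's double arm are combined
        (signed Stouffer) and BH-corrected across genes; a gene is
        evaluated when its combined FDR is below ``fdr_threshold``.
        Phenotype means use *all* constructs of each arm.  This pools the
        per-guide evidence, which matters because individual constructs
        near the background level carry little weight on their own.
    ``"construct"``
        A gene is evaluated when at least ``min_sig_constructs`` double-arm
        constructs pass the construct-level FDR gate; means run over the
        passing constructs only, and a single-knockout phenotype is
        believed (non-zero) only on the same footing.

    Genes failing the gate are reported NOT_SIGNIFICANT; genes whose
    adjusted double phenotype is not a depletion are UNDEFINED and never
    called.
    """
    table = diff.table if isinstance(diff, DifferentialResult) else diff
    if isinstance(library, pd.DataFrame):
        lib_rows = library[["construct_id", "target1", "target2", "category"]].to_dict("records")
    else:
        lib_rows = [
            {
                "construct_id": c.id,
                "target1": c.guide1.target,
                "target2": c.guide2.target,
                "category": c.category.value,
            }
            for c in library
        ]
    known = {r["target1"] for r in lib_rows}
    if anchor not in known:
        raise ValueError(f"anchor gene {anchor!r} has no position-1 guides in the library")
    if not any(
        r["target1"] == anchor and r["target2"] == CONTROL for r in lib_rows
    ):
        raise ValueError("library has no anchor-control constructs; cannot remove the anchor effect")

    if gate not in ("gene", "construct"):
        raise ValueError(f"unknown gate mode {gate!r}")
    logfc = table["logFC"]
    pvalue = table["pvalue"]
    passing = set(table.index[table["fdr"] < fdr_threshold])

    # per gene: (logFC, pvalue, sign, passed) tuples for each arm
    single_arm: dict[str, list[tuple[float, float, bool]]] = {}
    double_arm: dict[str, list[tuple[float, float, bool]]] = {}
    anchor_vals: list[float] = []
    for r in lib_rows:
        cid = r["construct_id"]
        if cid not in table.index:
            continue
        t1, t2 = r["target1"], r["target2"]
        if t1 == anchor and t2 == CONTROL:
            anchor_vals.append(float(logfc[cid]))
            continue
        if t2 in (CONTROL, anchor):
            continue
        entry = (float(logfc[cid]), float(pvalue[cid]), cid in passing)
        if t1 == CONTROL:
            single_arm.setdefault(t2, []).append(entry)
        elif t1 == anchor:
            double_arm.setdefault(t2, []).append(entry)

    p_anchor = float(np.mean(anchor_vals)) if anchor_vals else 0.0
    genes = sorted(set(single_arm) | set(double_arm))

    def _fisher_gate(arm: dict[str, list[tuple[float, float, bool]]]) -> dict[str, bool]:
        # Fisher combination of an arm's construct p-values, BH corrected
        # across genes: consistent weak evidence across a gene's constructs
        # accumulates, while one aberrant construct cannot carry the gene
        combined: dict[str, float] = {}
        for g in genes:
            entries = arm.get(g, [])
            if not entries:
                continue
            stat = -2.0 * np.sum([np.log(max(p, 1e-300)) for _, p, _ in entries])
            combined[g] = float(sps.chi2.sf(stat, 2 * len(entries)))
        if not combined:
            return {}
        keys = list(combined)
        fdrs = multipletests([combined[k] for k in keys], method="fdr_bh")[1]
        return {k: f < fdr_threshold for k, f in zip(keys, fdrs)}

    gene_gate_pass: dict[str, bool] = {}
    single_gate_pass: dict[str, bool] = {}
    if gate == "gene":
        gene_gate_pass = _fisher_gate(double_arm)
        single_gate_pass = _fisher_gate(single_arm)

    rows = []
    for g in genes:
        singles_all = single_arm.get(g, [])
        doubles_all = double_arm.get(g, [])
        if gate == "gene":
            singles = [l for l, _, _ in singles_all]
            doubles = [l for l, _, _ in doubles_all]
            n_single_sig = sum(1 for _, _, ok in singles_all if ok)
            n_double_sig = sum(1 for _, _, ok in doubles_all if ok)
            p_single = (
                float(np.mean(singles)) if singles and single_gate_pass.get(g, False) else 0.0
            )
            evaluated = bool(doubles) and gene_gate_pass.get(g, False)
        else:
            singles = [l for l, _, ok in singles_all if ok]
            doubles = [l for l, _, ok in doubles_all if ok]
            n_single_sig = len(singles)
            n_double_sig = len(doubles)
            p_single = float(np.mean(singles)) if len(singles) >= min_sig_constructs else 0.0
            evaluated = len(doubles) >= min_sig_constructs
        if not evaluated:
            rows.append(
                dict(gene=g, p_single=p_single, p_double_raw=np.nan, p_anchor=p_anchor,
                     p_double_adj=np.nan, ratio=np.nan, n_single_sig=n_single_sig,
                     n_double_sig=n_double_sig, status=CallStatus.NOT_SIGNIFICANT.value, called=False)
            )
            continue
        p_double_raw = float(np.mean(doubles))
        if adjust == "subtract":
            p_double_adj = p_double_raw - p_anchor
        elif adjust == "divide":
            p_double_adj = p_double_raw / p_anchor if p_anchor != 0 else np.nan
        else:
            raise ValueError(f"unknown adjust mode {adjust!r}")
        status = CallStatus.NOT_CALLED
        ratio = np.nan
        called = False
        if not np.isfinite(p_double_adj) or p_double_adj >= -min_double_effect:
            status = CallStatus.UNDEFINED
        else:
            ratio = p_single / p_double_adj
            sign_ok = (p_single < 0) if require_single_depletion else True
            if sign_ok and ratio < ratio_threshold:
                status = CallStatus.CALLED
                called = True
        rows.append(
            dict(gene=g, p_single=p_single, p_double_raw=p_double_raw, p_anchor=p_anchor,
                 p_double_adj=p_double_adj, ratio=ratio, n_single_sig=n_single_sig,
                 n_double_sig=n_double_sig, status=status.value, called=called)
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["p_single", "p_double_raw", "p_anchor", "p_double_adj", "ratio",
                 "n_single_sig", "n_double_sig", "status", "called"]
    )


def score_screen(
    counts: pd.DataFrame,
    library: Sequence[DualConstruct] | pd.DataFrame,
    anchor: str,
    t0_samples: Sequence[str],
    t14_samples: Sequence[str],
    min_cpm: float = 5.0,
    min_samples: int = 2,
    ratio_threshold: float = 0.5,
    fdr_threshold: float = 0.1,
    dispersion: float | str | None = "tagwise",
    **call_kwargs,
) -> tuple[pd.DataFrame, DifferentialResult]:
    """Run the full chain: background -> filter -> TMM -> test -> calls."""
    if isinstance(library, pd.DataFrame):
        categories = dict(zip(library["construct_id"], library["category"]))
    else:
        categories = {c.id: c.category for c in library}
    corrected = background_correct(counts, categories)
    corrected = corrected[list(t0_samples) + list(t14_samples)]
    filtered, _ = cpm_filter(corrected, min_cpm=min_cpm, min_samples=min_samples)
    factors = tmm_factors(filtered)
    diff = differential_abundance(
        filtered, factors, t0_samples, t14_samples,
        dispersion=dispersion, fdr_threshold=fdr_threshold,
    )
    calls = call_interactions(
        diff, library, anchor,
        ratio_threshold=ratio_threshold, fdr_threshold=fdr_threshold, **call_kwargs,
    )
    return calls, diff
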