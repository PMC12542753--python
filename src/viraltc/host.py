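"""Host differential expression and arCOG-style category representation.

The differential-expression caller is a deliberately simple, documented
stand-in for a full RNA-seq model: counts are library-size normalised,
summed over replicates, and compared between infected and control with a
negative-binomial conditional exact test.  For replicate sums s1, s2 with
n = s1 + s2 and a moment-estimated common dispersion phi, the conditional
null distribution of s1 given n is

    P(k | n)  ∝  Γ(k + r1)/k!  ·  Γ(n - k + r2)/(n - k)!,   r_i = R_i / phi

(R_i = number of replicates), which is free of the unknown mean; phi -> 0
recovers the binomial conditional test on summed counts.  Two-sided
p-values sum all outcomes no more likely than the observed one.

Category representation follows the randomised-expectation convention: for
a category holding m of G genome genes and k of D differentially expressed
genes, pct_expected = 100·m/G, pct_observed = 100·k/D, fold =
pct_observed/pct_expected, displayed as fold when ≥ 1 and as -1/fold when
below 1 (so values in (-1, 1) never occur and under/over flip at 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

__all__ = ["call_degs", "enrich", "core_deg_sets", "UNKNOWN_CATEGORY"]

UNKNOWN_CATEGORY = "S"  # genes without a functional assignment


def _median_of_ratios(inf: np.ndarray, ctl: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column size factors as median count ratio to a geometric reference."""
    both = np.hstack([inf, ctl])
    positive = np.all(both > 0, axis=1)
    if not positive.any():
        sums = both.sum(axis=0)
        return sums[: inf.shape[1]], sums[inf.shape[1] :]
    ref = np.exp(np.log(both[positive]).mean(axis=1))
    sf = np.median(both[positive] / ref[:, None], axis=0)
    return sf[: inf.shape[1]], sf[inf.shape[1] :]


def _common_dispersion(norm_inf: np.ndarray, norm_ctrl: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from normalised replicate counts.

    Ratio estimator phi = sum_g (v_g - m_g) / sum_g m_g^2 pooled over both
    conditions (genes with mean >= 5); for NB counts E[v - m] = phi mu^2, so
    the ratio is nearly unbiased even with few replicates, where a median of
    per-gene estimates would be badly biased low.
    """
    num = 0.0
    den = 0.0
    for mat in (norm_inf, norm_ctrl):
        if mat.shape[1] < 2:
            continue
        m = mat.mean(axis=1)
        v = mat.var(axis=1, ddof=1)
        ok = m >= 5
        num += float(np.sum(v[ok] - m[ok]))
        den += float(np.sum(m[ok] ** 2))
    if den == 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 5.0))


def _exact_conditional_pvalue(k: int, n: int, r1: float, r2: float) -> float:
    """Two-sided exact p for s1 = k of n under the NB/binomial conditional null."""
    if n == 0:
        return 1.0
    ks = np.arange(n + 1)
    if np.isinf(r1) or np.isinf(r2):  # phi = 0: binomial with p = R1/(R1+R2) folded in by caller
        raise ValueError("use _binom_logpmf for zero dispersion")
    logp = (
        gammaln(ks + r1)
        - gammaln(ks + 1)
        + gammaln(n - ks + r2)
        - gammaln(n - ks + 1)
    )
    logp -= logsumexp(logp)
    obs = logp[k]
    keep = logp <= obs + 1e-10  # all outcomes no more likely than observed
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def _binom_conditional_pvalue(k: int, n: int, p0: float) -> float:
    if n == 0:
        return 1.0
    ks = np.arange(n + 1)
    logp = (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * np.log(p0)
        + (n - ks) * np.log1p(-p0)
    )
    obs = logp[k]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def call_degs(
    infected_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    *,
    lib_infected: np.ndarray | None = None,
    lib_control: np.ndarray | None = None,
    alpha: float = 0.05,
    lfc_floor: float = 0.0,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Call differentially expressed genes, infected vs uninfected control.

    ``infected_counts`` / ``control_counts`` are genes × replicates count
    matrices over the same gene index; library sizes default to column sums.
    Returns a per-gene table with ``log2_fold_change`` (of library-size
    normalised means, pseudocount 0.5), ``p_value`` from the exact
    conditional count test, and ``direction`` in {up, down, ns}.  ``adjust=
    "bh"`` applies Benjamini-Hochberg before thresholding (off by default,
    mirroring a raw p < alpha convention).
    """
    if not infected_counts.index.equals(control_counts.index):
        raise ValueError("infected and control gene universes differ")
    inf = infected_counts.to_numpy(float)
    ctl = control_counts.to_numpy(float)
    if lib_infected is None and lib_control is None:
        # median-of-ratios size factors: robust to asymmetric differential
        # expression, which would bias plain column totals
        lib_i, lib_c = _median_of_ratios(inf, ctl)
    else:
        lib_i = np.asarray(lib_infected if lib_infected is not None else inf.sum(axis=0), float)
        lib_c = np.asarray(lib_control if lib_control is not None else ctl.sum(axis=0), float)
    if np.any(lib_i <= 0) or np.any(lib_c <= 0):
        raise ValueError("library sizes must be positive")
    scale = np.concatenate([lib_i, lib_c]).mean()
    norm_i = inf * (scale / lib_i)
    norm_c = ctl * (scale / lib_c)
    R1, R2 = inf.shape[1], ctl.shape[1]

    mean_i = norm_i.mean(axis=1)
    mean_c = norm_c.mean(axis=1)
    lfc = np.log2((mean_i + 0.5) / (mean_c + 0.5))

    phi = _common_dispersion(norm_i, norm_c)
    s1 = np.rint(norm_i.sum(axis=1)).astype(int)
    s2 = np.rint(norm_c.sum(axis=1)).astype(int)
    n = s1 + s2
    pvals = np.ones(len(n))
    if phi <= 1e-8:
        p0 = R1 / (R1 + R2)
        for g in range(len(n)):
            pvals[g] = _binom_conditional_pvalue(s1[g], n[g], p0)
    else:
        r1, r2 = R1 / phi, R2 / phi
        for g in range(len(n)):
            pvals[g] = _exact_conditional_pvalue(s1[g], n[g], r1, r2)

    p_for_call = pvals
    if adjust == "bh":
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate((pvals[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        p_for_call = np.minimum(adj, 1.0)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    sig = (p_for_call < alpha) & (np.abs(lfc) >= lfc_floor)
    direction = np.where(~sig, "ns", np.where(lfc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "mean_infected": mean_i,
            "mean_control": mean_c,
            "log2_fold_change": lfc,
            "p_value": pvals,
            "direction": direction,
        },
        index=infected_counts.index.rename("gene"),
    )


def enrich(
    deg_genes,
    category_map: pd.Series | dict,
    *,
    genome_size: int | None = None,
    direction: str = "",
    hypergeometric: bool = False,
) -> pd.DataFrame:
    """Fold over-/underrepresentation of each category among a DEG set.

    ``category_map`` maps every genome gene to a category letter; genes
    missing from the map are pooled into the unknown category "S" only if
    explicitly present in ``deg_genes`` (the map should normally be total).
    ``genome_size`` defaults to the size of the map.  Returns one row per
    category with ≥ 1 genome gene; ``signed_representation`` is fold for
    fold ≥ 1 and -1/fold otherwise.  With ``hypergeometric=True`` a
    hypergeometric tail p-value is added (enrichment tail for fold ≥ 1,
    depletion tail otherwise).
    """
    cat = pd.Series(category_map).astype(str)
    deg_genes = list(deg_genes)
    deg_cats = []
    for g in deg_genes:
        deg_cats.append(cat.get(g, UNKNOWN_CATEGORY))
    G = int(genome_size) if genome_size is not None else int(len(cat))
    D = len(deg_genes)
    if D == 0:
        warnings.warn("no differentially expressed genes; enrichment omitted", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "category", "direction", "category_size", "genome_size",
                "deg_count_in_category", "deg_total", "pct_expected",
                "pct_observed", "fold", "signed_representation",
            ]
        )
    cat_sizes = cat.value_counts()
    if G > len(cat):
        # genes in the universe but absent from the map count as unknown
        cat_sizes[UNKNOWN_CATEGORY] = cat_sizes.get(UNKNOWN_CATEGORY, 0) + (G - len(cat))
    deg_counts = pd.Series(deg_cats).value_counts()
    rows = []
    for letter, m in sorted(cat_sizes.items()):
        k = int(deg_counts.get(letter, 0))
        pct_exp = 100.0 * m / G
        pct_obs = 100.0 * k / D
        fold = pct_obs / pct_exp
        signed = fold if fold >= 1 else (-np.inf if fold == 0 else -1.0 / fold)
        row = {
            "category": letter,
            "direction": direction,
            "category_size": int(m),
            "genome_size": G,
            "deg_count_in_category": k,
            "deg_total": D,
            "pct_expected": pct_exp,
            "pct_observed": pct_obs,
            "fold": fold,
            "signed_representation": signed,
        }
        if hypergeometric:
            if fold >= 1:
                row["p_hypergeom"] = float(hypergeom.sf(k - 1, G, int(m), D))
            else:
                row["p_hypergeom"] = float(hypergeom.cdf(k, G, int(m), D))
        rows.append(row)
    return pd.DataFrame(rows)


def core_deg_sets(deg_sets: dict) -> dict:
    """Set algebra over per-timepoint DEG sets (one direction).

    ``deg_sets`` maps timepoint -> set of gene ids.  Returns the core set
    (genes differential at every timepoint) and, per timepoint, the genes
    exclusive to it.
    """
    if len(deg_sets) < 1:
        raise ValueError("need at least one timepoint")
    tps = sorted(deg_sets)
    core = set(deg_sets[tps[0]])
    for t in tps[1:]:
        core &= set(deg_sets[t])
    exclusive = {}
    for t in tps:
        others = set().union(*(deg_sets[o] for o in tps if o != t)) if len(tps) > 1 else set()
        exclusive[t] = set(deg_sets[t]) - others
    return {"core": core, "exclusive": exclusive}
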