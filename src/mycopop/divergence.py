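"""Weir-Cockerham F_ST, windowed divergence, and a Bayesian outlier scan.

Site F_ST is the Weir & Cockerham (1984) variance-component estimator
theta = a/(a+b+c) on diploid genotypes, with observed heterozygote counts
feeding the among-individual (b) and within-individual (c) components.
Window F_ST aggregates by ratio-of-sums, sum(a)/sum(a+b+c) (the weighted,
VCFtools-style windowed convention).

The outlier scan re-implements the multinomial-Dirichlet (here: biallelic,
hence beta-binomial) logistic-regression model of F_ST at desk scale: for
locus i and population j,

    logit(F_ij) = alpha_i * delta_i + beta_j,

population allele frequencies follow a beta distribution around the
ancestral frequency p_i with precision (1 - F_ij)/F_ij, and observed allele
counts are binomial draws.  A reversible-jump MCMC toggles the locus effect
alpha_i in and out of the model with configurable prior odds for the neutral
model; the posterior inclusion probability yields a posterior error
probability PEP = 1 - P(inclusion) and q-values as running means of sorted
PEPs.  Strains labeled "outlier" (hybrids) are excluded from all
between-group scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .core import MISSING, GenotypeMatrix, GroupAssignment

__all__ = [
    "wc_fst_sites",
    "wc_fst_windows",
    "multipop_fst",
    "top_fraction_windows",
    "allele_counts_by_population",
    "McmcSettings",
    "OutlierScanResult",
    "bayesian_outlier_scan",
    "q_values",
    "call_outliers",
    "assign_candidate_divergence_snps",
    "candidate_genes",
]


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984)


def _pop_summaries(
    matrix: GenotypeMatrix, assignment: GroupAssignment, groups: list[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (pop, locus): sample size n, alt frequency p, het proportion h."""
    n = np.zeros((len(groups), matrix.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, g in enumerate(groups):
        idx = [matrix.strains.index(s) for s in assignment.members(g)]
        d = matrix.dosages[idx, :]
        called = d != MISSING
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, d, 0).sum(axis=0) / np.maximum(2 * n[k], 1)
            h[k] = (d == 1).sum(axis=0) / np.maximum(n[k], 1)
    return n, p, h


def wc_fst_sites(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Per-site Weir-Cockerham variance components and theta.

    ``groups`` selects the populations compared (default: all non-outlier
    groups).  Returns (scaffold, pos, a, b, c, theta); theta is NaN where the
    denominator a+b+c is zero (e.g. monomorphic sites) or where fewer than
    two populations have two or more called strains.
    """
    groups = list(groups) if groups is not None else assignment.groups()
    if len(groups) < 2:
        raise ValueError("need >= 2 populations for F_ST")
    n, p, h = _pop_summaries(matrix, assignment, groups)
    r = len(groups)
    usable = (n >= 2).sum(axis=0) >= 2
    nbar = n.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where((denom != 0) & usable, a / np.where(denom == 0, 1, denom),
                         np.nan)
    out = matrix.loci[["scaffold", "pos"]].copy()
    out["a"] = np.where(usable, a, np.nan)
    out["b"] = np.where(usable, b, np.nan)
    out["c"] = np.where(usable, c, np.nan)
    out["theta"] = theta
    return out


def multipop_fst(sites: pd.DataFrame) -> float:
    """Genome-wide weighted (ratio-of-sums) theta over all defined sites."""
    ok = sites[["a", "b", "c"]].notna().all(axis=1)
    num = sites.loc[ok, "a"].sum()
    den = (sites.loc[ok, ["a", "b", "c"]].to_numpy()).sum()
    return float(num / den) if den else float("nan")


def wc_fst_windows(sites: pd.DataFrame, window_size: int = 5000) -> pd.DataFrame:
    """Windowed theta by ratio-of-sums over the sites in each tiled window.

    Windows with no defined site carry theta = NaN (flagged, still listed).
    """
    rows = []
    for scaf, sub in sites.groupby("scaffold", sort=False):
        pos = sub["pos"].to_numpy()
        widx = (pos - 1) // window_size
        n_windows = int(widx.max()) + 1 if len(widx) else 0
        for w in range(n_windows):
            block = sub[widx == w]
            ok = block[["a", "b", "c"]].notna().all(axis=1)
            num = block.loc[ok, "a"].sum()
            den = block.loc[ok, ["a", "b", "c"]].to_numpy().sum()
            rows.append(
                {
                    "scaffold": scaf,
                    "start": w * window_size + 1,
                    "end": (w + 1) * window_size,
                    "n_sites": int(ok.sum()),
                    "fst_num": float(num),
                    "fst_den": float(den),
                    "fst": float(num / den) if den else float("nan"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "n_sites", "fst_num", "fst_den", "fst"],
    )


def top_fraction_windows(windows: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Nearest-rank selection of the highest-F_ST windows.

    Keeps the ceil(fraction * N_defined) highest-theta windows among windows
    with a defined theta; all windows tied with the cutoff value are kept.
    Output is ordered by (theta desc, scaffold, start).
    """
    defined = windows.dropna(subset=["fst"]).copy()
    if defined.empty:
        return defined
    k = int(np.ceil(fraction * len(defined)))
    defined = defined.sort_values(
        ["fst", "scaffold", "start"], ascending=[False, True, True]
    )
    cutoff = defined["fst"].iloc[k - 1]
    return defined[defined["fst"] >= cutoff].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bayesian outlier scan


def allele_counts_by_population(
    matrix: GenotypeMatrix,
    assignment: GroupAssignment,
    groups: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Alt-allele counts and total called alleles per (locus, population)."""
    groups = list(groups) if groups is not None else assignment.groups()
    alt = np.zeros((matrix.n_loci, len(groups)), dtype=np.int64)
    tot = np.zeros_like(alt)
    for k, g in enumerate(groups):
        idx = [matrix.strains.index(s) for s in assignment.members(g)]
        d = matrix.dosages[idx, :]
        called = d != MISSING
        alt[:, k] = np.where(called, d, 0).sum(axis=0)
        tot[:, k] = 2 * called.sum(axis=0)
    return alt, tot, groups


@dataclass
class McmcSettings:
    """Chain-length and proposal settings for the reversible-jump sampler."""

    burn_in: int = 5000
    n_iter: int = 20000
    thin: int = 10
    prop_p: float = 0.06
    prop_alpha: float = 0.6
    prop_beta: float = 0.25
    adapt_interval: int = 250  # pilot adaptation of proposal widths (burn-in only)
    alpha_prior_sd: float = 2.0
    beta_prior_mean: float = -1.0
    beta_prior_sd: float = 1.8
    mcse_threshold: float = 0.1  # split-half inclusion-probability disagreement


@dataclass
class OutlierScanResult:
    """Posterior summaries of the outlier scan.

    ``loci`` columns: alpha (posterior mean locus effect given inclusion),
    inclusion_prob, pep, q_value, fst (posterior mean per-locus F_ST averaged
    over populations).
    """

    loci: pd.DataFrame
    beta: pd.DataFrame  # per-population effect posterior mean
    global_fst: float
    settings: McmcSettings
    seed: int
    prior_odds: float
    max_split_disagreement: float = float("nan")
    converged: bool = True
    groups: list[str] = field(default_factory=list)


def _beta_binom_ll(
    alt: np.ndarray, tot: np.ndarray, p: np.ndarray, logit_f: np.ndarray
) -> np.ndarray:
    """Beta-binomial log-likelihood matrix (binomial coefficient dropped).

    ``p`` is per-locus (column vector broadcast over populations);
    ``logit_f`` the (loci x pops) matrix alpha*delta + beta.
    """
    theta = np.exp(-logit_f)  # (1-F)/F for F = expit(logit_f)
    tp = theta * p[:, None]
    tq = theta * (1.0 - p[:, None])
    return (
        gammaln(theta)
        - gammaln(theta + tot)
        + gammaln(tp + alt)
        - gammaln(tp)
        + gammaln(tq + tot - alt)
        - gammaln(tq)
    )


def q_values(pep: np.ndarray) -> np.ndarray:
    """q_i = mean PEP over loci with PEP <= PEP_i (FDR analogue)."""
    pep = np.asarray(pep, dtype=float)
    order = np.argsort(pep, kind="stable")
    sorted_pep = pep[order]
    cummean = np.cumsum(sorted_pep) / np.arange(1, len(pep) + 1)
    # ties: every locus sharing a PEP gets the q of the last tied position
    q_sorted = cummean.copy()
    i = len(pep) - 1
    while i > 0:
        if sorted_pep[i - 1] == sorted_pep[i]:
            q_sorted[i - 1] = q_sorted[i]
        i -= 1
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def bayesian_outlier_scan(
    alt: np.ndarray,
    tot: np.ndarray,
    prior_odds: float = 10.0,
    settings: McmcSettings | None = None,
    seed: int = 0,
    groups: list[str] | None = None,
    loci: pd.DataFrame | None = None,
) -> OutlierScanResult:
    """Reversible-jump MCMC scan for loci with population-specific selection.

    Parameters
    ----------
    alt, tot
        (n_loci, n_pops) alternate-allele counts and total called alleles.
    prior_odds
        Prior odds in favor of the neutral (no locus effect) model.
    settings
        Chain settings; proposal widths are pilot-adapted during burn-in.
    seed
        Seed for the chain's generator; fixed seed gives identical results.

    Notes
    -----
    All locus-level updates are vectorized across loci (loci are
    conditionally independent given the population effects beta), so the
    chain costs a few dense (loci x pops) likelihood evaluations per sweep.
    """
    settings = settings or McmcSettings()
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(tot, dtype=float)
    if alt.ndim != 2 or alt.shape != tot.shape:
        raise ValueError("alt/tot must be matching (n_loci, n_pops) arrays")
    n_loci, n_pops = alt.shape
    if n_pops < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)

    # initial state: empirical frequencies, neutral model everywhere
    p = np.clip(alt.sum(axis=1) / np.maximum(tot.sum(axis=1), 1), 0.01, 0.99)
    alpha = np.zeros(n_loci)
    delta = np.zeros(n_loci, dtype=bool)
    beta = np.full(n_pops, settings.beta_prior_mean)
    w_p, w_a, w_b = settings.prop_p, settings.prop_alpha, settings.prop_beta
    log_prior_odds = np.log(prior_odds)

    def loglik(p_, alpha_, delta_, beta_):
        logit_f = np.where(delta_[:, None], alpha_[:, None], 0.0) + beta_[None, :]
        return _beta_binom_ll(alt, tot, p_, logit_f)

    ll = loglik(p, alpha, delta, beta)

    keep_every = settings.thin
    n_samples = settings.n_iter // keep_every
    incl_samples = np.zeros((n_samples, n_loci), dtype=bool)
    fst_sum = np.zeros(n_loci)
    alpha_sum = np.zeros(n_loci)
    alpha_n = np.zeros(n_loci)
    beta_sum = np.zeros(n_pops)
    sample_i = 0
    acc = {"p": 0, "alpha": 0, "beta": 0}
    tries = {"p": 0, "alpha": 0, "beta": 0}

    total_iters = settings.burn_in + settings.n_iter
    for it in range(total_iters):
        # -- ancestral frequencies (uniform prior, symmetric proposal)
        p_prop = p + rng.normal(0.0, w_p, size=n_loci)
        valid = (p_prop > 0.0) & (p_prop < 1.0)
        p_try = np.where(valid, p_prop, p)
        ll_prop = loglik(p_try, alpha, delta, beta)
        log_r = (ll_prop - ll).sum(axis=1)
        accept = valid & (np.log(rng.random(n_loci)) < log_r)
        p = np.where(accept, p_try, p)
        ll[accept] = ll_prop[accept]
        tries["p"] += n_loci
        acc["p"] += int(accept.sum())

        # -- locus effects for included loci (normal prior, random walk)
        if delta.any():
            a_prop = alpha + rng.normal(0.0, w_a, size=n_loci)
            ll_prop = loglik(p, a_prop, delta, beta)
            log_r = (ll_prop - ll).sum(axis=1) + (
                alpha**2 - a_prop**2
            ) / (2.0 * settings.alpha_prior_sd**2)
            accept = delta & (np.log(rng.random(n_loci)) < log_r)
            alpha = np.where(accept, a_prop, alpha)
            ll[accept] = ll_prop[accept]
            tries["alpha"] += int(delta.sum())
            acc["alpha"] += int(accept.sum())

        # -- reversible-jump toggle (birth proposal = prior, so prior terms
        #    cancel and only the likelihood ratio and model prior odds remain)
        a_birth = rng.normal(0.0, settings.alpha_prior_sd, size=n_loci)
        delta_prop = ~delta
        a_prop = np.where(delta, 0.0, a_birth)  # value if the toggle happens
        ll_prop = loglik(p, a_prop, delta_prop, beta)
        log_r = (ll_prop - ll).sum(axis=1) + np.where(
            delta, log_prior_odds, -log_prior_odds
        )
        accept = np.log(rng.random(n_loci)) < log_r
        alpha = np.where(accept, a_prop, alpha)
        delta = np.where(accept, delta_prop, delta)
        ll[accept] = ll_prop[accept]

        # -- population effects (normal prior, random walk, one at a time)
        for j in range(n_pops):
            b_prop = beta.copy()
            b_prop[j] += rng.normal(0.0, w_b)
            logit_col = np.where(delta, alpha, 0.0) + b_prop[j]
            ll_col = _beta_binom_ll(
                alt[:, j : j + 1], tot[:, j : j + 1], p, logit_col[:, None]
            )[:, 0]
            log_r = (
                ll_col.sum()
                - ll[:, j].sum()
                + ((beta[j] - settings.beta_prior_mean) ** 2
                   - (b_prop[j] - settings.beta_prior_mean) ** 2)
                / (2.0 * settings.beta_prior_sd**2)
            )
            tries["beta"] += 1
            if np.log(rng.random()) < log_r:
                beta = b_prop
                ll[:, j] = ll_col
                acc["beta"] += 1

        # -- pilot adaptation during burn-in
        if it < settings.burn_in and (it + 1) % settings.adapt_interval == 0:
            for key, width in (("p", "w_p"), ("alpha", "w_a"), ("beta", "w_b")):
                if tries[key] == 0:
                    continue
                rate = acc[key] / tries[key]
                scale = 1.25 if rate > 0.45 else (0.8 if rate < 0.2 else 1.0)
                if key == "p":
                    w_p = float(np.clip(w_p * scale, 1e-3, 0.5))
                elif key == "alpha":
                    w_a = float(np.clip(w_a * scale, 0.05, 3.0))
                else:
                    w_b = float(np.clip(w_b * scale, 0.02, 2.0))
                acc[key] = 0
                tries[key] = 0

        # -- record
        if it >= settings.burn_in and (it - settings.burn_in + 1) % keep_every == 0:
            incl_samples[sample_i] = delta
            logit_f = np.where(delta[:, None], alpha[:, None], 0.0) + beta[None, :]
            fst_sum += expit(logit_f).mean(axis=1)
            alpha_sum += np.where(delta, alpha, 0.0)
            alpha_n += delta
            beta_sum += beta
            sample_i += 1

    incl = incl_samples[:sample_i].mean(axis=0)
    pep = 1.0 - incl
    q = q_values(pep)
    fst = fst_sum / max(sample_i, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha_mean = np.where(alpha_n > 0, alpha_sum / np.maximum(alpha_n, 1), 0.0)

    half = sample_i // 2
    disagreement = float(
        np.abs(
            incl_samples[:half].mean(axis=0) - incl_samples[half:sample_i].mean(axis=0)
        ).max()
    ) if half else float("nan")
    converged = not (half and disagreement > settings.mcse_threshold)
    if not converged:
        warnings.warn(
            "outlier scan may not have converged: split-half inclusion "
            f"probabilities disagree by up to {disagreement:.3f} "
            f"(threshold {settings.mcse_threshold}); consider longer chains"
        )

    loci_df = (
        loci[["scaffold", "pos"]].copy()
        if loci is not None
        else pd.DataFrame({"locus": np.arange(n_loci)})
    )
    loci_df["alpha"] = alpha_mean
    loci_df["inclusion_prob"] = incl
    loci_df["pep"] = pep
    loci_df["q_value"] = q
    loci_df["fst"] = fst
    beta_df = pd.DataFrame(
        {
            "population": groups if groups is not None else list(range(n_pops)),
            "beta": beta_sum / max(sample_i, 1),
        }
    )
    return OutlierScanResult(
        loci=loci_df,
        beta=beta_df,
        global_fst=float(np.nanmean(fst)),
        settings=settings,
        seed=seed,
        prior_odds=prior_odds,
        max_split_disagreement=disagreement,
        converged=converged,
        groups=list(groups) if groups is not None else [],
    )


def call_outliers(scan: OutlierScanResult, q_threshold: float = 0.05) -> pd.DataFrame:
    """Loci with q below threshold AND posterior F_ST above the scan mean."""
    mean_fst = scan.loci["fst"].mean()
    mask = (scan.loci["q_value"] < q_threshold) & (scan.loci["fst"] > mean_fst)
    return scan.loci[mask].reset_index(drop=True)


# ---------------------------------------------------------------------------
# candidate-divergence set logic


def _window_key(scaffold: pd.Series, pos: pd.Series, window_size: int) -> pd.Series:
    return scaffold.astype(str) + ":" + ((pos - 1) // window_size).astype(str)


def assign_candidate_divergence_snps(
    outliers: pd.DataFrame,
    top_windows_by_pair: dict[tuple[str, str], pd.DataFrame],
    window_size: int = 5000,
) -> pd.DataFrame:
    """Assign each outlier SNP to the group(s) whose divergence it supports.

    A SNP supports the divergence of group X iff it falls inside a top-F_ST
    window of BOTH pairwise comparisons involving X.  A SNP inside all three
    pairs' windows is assigned to all three groups; a SNP inside at most one
    pair's windows gets an empty assignment but keeps its per-pair flags (for
    Venn-style tallies).  The result is independent of pair-processing order.

    Returns one row per outlier SNP: scaffold, pos, in_<A>_<B> flags per
    pair, and ``groups`` (comma-joined sorted labels, may be empty).
    """
    pairs = {tuple(sorted(k)): v for k, v in top_windows_by_pair.items()}
    all_groups = sorted({g for pair in pairs for g in pair})
    out = outliers[["scaffold", "pos"]].copy()
    snp_key = _window_key(out["scaffold"], out["pos"], window_size)
    membership: dict[tuple[str, str], pd.Series] = {}
    for pair in sorted(pairs):
        win = pairs[pair]
        keys = set(
            _window_key(win["scaffold"], win["start"], window_size)
        ) if len(win) else set()
        flag = snp_key.isin(keys)
        membership[pair] = flag
        out[f"in_{pair[0]}_{pair[1]}"] = flag
    assigned = []
    for i in range(len(out)):
        gs = []
        for g in all_groups:
            involving = [pair for pair in pairs if g in pair]
            if len(involving) >= 2 and all(membership[pair].iloc[i] for pair in involving):
                gs.append(g)
        assigned.append(",".join(gs))
    out["groups"] = pd.Series(assigned, index=out.index, dtype=object)
    return out


def candidate_genes(
    assignment: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per-group candidate gene lists and the gene-sharing report.

    Maps each assigned SNP to its overlapping gene via the annotation table
    (intergenic SNPs contribute nothing) and deduplicates per group.  The
    report lists each gene with the sorted group combination it supports.
    """
    ann = assignment.merge(
        annotation[["scaffold", "pos", "gene_id"]], on=["scaffold", "pos"], how="left"
    )
    per_group: dict[str, set[str]] = {}
    for row in ann.itertuples():
        gene = getattr(row, "gene_id", "")
        if not isinstance(gene, str) or gene == "" or not row.groups:
            continue
        for g in row.groups.split(","):
            per_group.setdefault(g, set()).add(gene)
    gene_groups: dict[str, set[str]] = {}
    for g, genes in per_group.items():
        for gene in genes:
            gene_groups.setdefault(gene, set()).add(g)
    report = pd.DataFrame(
        sorted(
            (gene, ",".join(sorted(gs)), len(gs)) for gene, gs in gene_groups.items()
        ),
        columns=["gene_id", "groups", "n_groups"],
    )
    return {g: sorted(s) for g, s in sorted(per_group.items())}, report
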