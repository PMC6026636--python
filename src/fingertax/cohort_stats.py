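"""Two-cohort comparison statistics.

Covers the full comparative toolkit of the study design: 2x2 contingency
tests for clinical covariates, pooled-variance t-tests, Chao1 richness,
the whole-community Dirichlet-Multinomial likelihood-ratio test,
Bray-Curtis ordination (classical-scaling PCoA) with PAM clustering,
Pearson similarity matrices, two-log fold-change differential gene
calling, and taxon biplot vectors.

The Dirichlet-Multinomial (DM) model is parameterised by the mean
composition pi (sums to 1) and overdispersion theta in [0, 1); with
alpha_i = pi_i (1 - theta) / theta the DM probability mass of a count
vector x with total N is

    C(N; x) * Gamma(A) / Gamma(N + A) * prod_i Gamma(x_i + alpha_i) / Gamma(alpha_i),

A = sum alpha = (1 - theta) / theta. theta -> 0 recovers the multinomial.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, digamma
from skbio.diversity.alpha import chao1 as _skbio_chao1

logger = logging.getLogger(__name__)


def _digest(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a, dtype=float).tobytes())
    return h.hexdigest()[:12]


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    tail: str = "two-sided"
    extra: dict = field(default_factory=dict)
    inputs_digest: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test_name, "statistic": self.statistic,
            "p_value": self.p_value, "df": self.df, "tail": self.tail,
            **{f"extra_{k}": v for k, v in self.extra.items()},
        }


# ---------------------------------------------------------------------------
# Contingency and t-tests

def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's. Pearson chi-squared statistics (with and without Yates
    continuity correction) are attached in ``extra`` for the cases where a
    chi-squared test would be preferred.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("empty table")
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    extra = {"odds_ratio": float(odds)}
    if (t.sum(axis=0) > 0).all() and (t.sum(axis=1) > 0).all():
        chi2_c, p_c, _, _ = stats.chi2_contingency(t, correction=True)
        chi2_u, p_u, _, _ = stats.chi2_contingency(t, correction=False)
        extra.update(chi2_corrected=float(chi2_c), chi2_corrected_p=float(p_c),
                     chi2=float(chi2_u), chi2_p=float(p_u))
    return TestResult("fisher_exact", float(odds), float(p), df=None,
                      extra=extra, inputs_digest=_digest(t))


def two_sample_t(x, y, tails: int = 2) -> TestResult:
    """Unpaired Student t-test with pooled variance.

    ``tails=2`` for clinical continuous covariates; ``tails=1`` tests in
    the direction of the observed mean difference (the direction used is
    recorded in ``tail``). Degenerate zero pooled variance gives p = 1
    for equal means and a flagged p = 0 for separated means.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    dfree = x.size + y.size - 2
    diff = x.mean() - y.mean()
    pooled = (((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
              / dfree)
    if pooled == 0.0:
        if diff == 0.0:
            return TestResult("student_t", 0.0, 1.0, df=dfree,
                              tail="two-sided" if tails == 2 else "one-sided",
                              extra={"degenerate": True},
                              inputs_digest=_digest(x, y))
        return TestResult("student_t", np.inf if diff > 0 else -np.inf, 0.0,
                          df=dfree, tail="separated",
                          extra={"degenerate": True},
                          inputs_digest=_digest(x, y))
    if tails == 2:
        t, p = stats.ttest_ind(x, y, equal_var=True)
        tail = "two-sided"
    else:
        alt = "greater" if diff >= 0 else "less"
        t, p = stats.ttest_ind(x, y, equal_var=True, alternative=alt)
        tail = f"one-sided-{alt}"
    return TestResult("student_t", float(t), float(p), df=dfree, tail=tail,
                      inputs_digest=_digest(x, y))


# ---------------------------------------------------------------------------
# Alpha diversity

def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness from singleton/doubleton counts.

    Classic: S_obs + F1^2 / (2 F2); bias-corrected (default, and always
    used when F2 = 0): S_obs + F1 (F1 - 1) / (2 (F2 + 1)).
    """
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if counts.sum() == 0:
        return 0.0
    f2 = int((counts == 2).sum())
    if not bias_corrected and f2 == 0:
        bias_corrected = True
    return float(_skbio_chao1(counts.astype(int), bias_corrected=bias_corrected))


# ---------------------------------------------------------------------------
# Dirichlet-Multinomial likelihood machinery

@dataclass
class DMParams:
    """Mean composition pi (sums to 1) and overdispersion theta in [0, 1)."""

    pi: np.ndarray
    theta: float
    converged: bool = True
    loglik: float | None = None

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be non-negative and sum to 1 within 1e-9")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")

    @property
    def alpha(self) -> np.ndarray:
        if self.theta == 0.0:
            raise ValueError("theta = 0 has no finite alpha")
        return self.pi * (1.0 - self.theta) / self.theta


def _multinomial_loglik(x: np.ndarray, pi: np.ndarray) -> float:
    n = x.sum(axis=1)
    const = gammaln(n + 1).sum() - gammaln(x + 1).sum()
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    terms = np.where(x > 0, x * logpi, 0.0)
    if np.isneginf(logpi[(x > 0).any(axis=0)]).any():
        return -np.inf
    return float(const + terms.sum())


def _dm_loglik_alpha(x: np.ndarray, alpha: np.ndarray) -> float:
    n = x.sum(axis=1)
    a = alpha.sum()
    const = gammaln(n + 1).sum() - gammaln(x + 1).sum()
    return float(const
                 + x.shape[0] * gammaln(a) - gammaln(n + a).sum()
                 + gammaln(x + alpha).sum() - x.shape[0] * gammaln(alpha).sum())


def dm_loglik(counts, params: DMParams) -> float:
    """Log-likelihood of a samples x taxa count matrix under DM(pi, theta).

    theta = 0 is the exact multinomial limit. A taxon with pi = 0 but a
    positive observed count gives -inf.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if (x < 0).any() or (x.sum(axis=1) < 1).any():
        raise ValueError("counts must be non-negative with row sums >= 1")
    if params.theta == 0.0:
        return _multinomial_loglik(x, params.pi)
    if ((params.pi == 0) & (x > 0).any(axis=0)).any():
        return -np.inf
    obs = params.pi > 0
    return _dm_loglik_alpha(x[:, obs], params.alpha[obs])


def _fit_mom(x: np.ndarray) -> DMParams:
    """Method-of-moments start: pooled proportions and a variance-based theta."""
    n = x.sum(axis=1)
    pi = x.sum(axis=0) / x.sum()
    p = x / n[:, None]
    nbar = n.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = p.var(axis=0, ddof=1)
        denom = pi * (1 - pi)
        ratio = np.where(denom > 0, v / denom, np.nan)
    r = np.nanmean(ratio)
    # E[Var(p)] ~ pi(1-pi) (theta + (1-theta)/nbar)
    theta = (r - 1.0 / nbar) / (1.0 - 1.0 / nbar) if nbar > 1 else 0.0
    theta = float(np.clip(np.nan_to_num(theta), 1e-8, 1 - 1e-8))
    return DMParams(pi, theta)


def fit_dm(counts, maxiter: int = 500) -> DMParams:
    """Maximum-likelihood DM fit of a samples x taxa count matrix.

    Method-of-moments initialisation refined by L-BFGS-B on log alpha with
    the analytic gradient; theta is clamped to [1e-8, 1 - 1e-8]. On
    optimizer failure the MoM estimate is returned with ``converged``
    False.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a samples x taxa matrix with >= 2 samples")
    observed = x.sum(axis=0) > 0
    if observed.sum() < 2:
        pi = np.zeros(x.shape[1])
        pi[observed] = 1.0
        logger.warning("single observed taxon: theta unidentifiable")
        return DMParams(pi, 1e-8, converged=False,
                        loglik=dm_loglik(x, DMParams(pi, 1e-8)))
    xo = x[:, observed]
    n = xo.sum(axis=1)
    start = _fit_mom(xo)
    pi0 = np.clip(start.pi, 1e-10, None)
    pi0 /= pi0.sum()
    z0 = np.log(pi0 * (1 - start.theta) / start.theta)

    def negloglik_and_grad(z):
        alpha = np.exp(np.clip(z, -30, 30))
        a = alpha.sum()
        ll = (xo.shape[0] * gammaln(a) - gammaln(n + a).sum()
              + gammaln(xo + alpha).sum()
              - xo.shape[0] * gammaln(alpha).sum())
        g_alpha = (xo.shape[0] * digamma(a) - digamma(n + a).sum()
                   + digamma(xo + alpha).sum(axis=0)
                   - xo.shape[0] * digamma(alpha))
        return -ll, -(g_alpha * alpha)

    res = optimize.minimize(negloglik_and_grad, z0, jac=True,
                            method="L-BFGS-B",
                            options={"maxiter": maxiter})
    if res.success:
        alpha = np.exp(np.clip(res.x, -30, 30))
        a = alpha.sum()
        pi = np.zeros(x.shape[1])
        pi[observed] = alpha / a
        theta = float(np.clip(1.0 / (1.0 + a), 1e-8, 1 - 1e-8))
        params = DMParams(pi, theta, converged=True)
    else:
        logger.warning("DM fit did not converge; returning MoM estimate")
        pi = np.zeros(x.shape[1])
        pi[observed] = start.pi
        params = DMParams(pi, start.theta, converged=False)
    params.loglik = dm_loglik(x, params)
    return params


def dm_lrt(counts_a, counts_b) -> TestResult:
    """Whole-community likelihood-ratio test between two cohorts.

    Both matrices (samples x shared taxa, ideally rarefied to a common
    depth first) are fit separately and pooled; the statistic
    -2 (l_pooled - l_A - l_B) is referenced to chi-square with
    df = K (G - 1), K = (n_taxa - 1) + 1 free parameters per group, G = 2.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs >= 2 samples")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share taxon columns")
    fit_a = fit_dm(a)
    fit_b = fit_dm(b)
    fit_p = fit_dm(np.vstack([a, b]))
    if not (fit_a.converged and fit_b.converged and fit_p.converged):
        logger.warning("dm_lrt: at least one DM fit used the MoM fallback")
    stat = max(0.0, -2.0 * (fit_p.loglik - fit_a.loglik - fit_b.loglik))
    df = a.shape[1]  # (K_taxa - 1) proportions + 1 overdispersion, G - 1 = 1
    p = float(stats.chi2.sf(stat, df))
    return TestResult("dm_lrt", float(stat), p, df=df,
                      extra={"loglik_pooled": fit_p.loglik,
                             "loglik_a": fit_a.loglik,
                             "loglik_b": fit_b.loglik,
                             "theta_a": fit_a.theta, "theta_b": fit_b.theta,
                             "df_convention": "K*(G-1), K=(taxa-1)+1"},
                      inputs_digest=_digest(a, b))


# ---------------------------------------------------------------------------
# Beta diversity, ordination, clustering

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between samples (rows)."""
    x = table.to_numpy(dtype=float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return pd.DataFrame(d, index=table.index, columns=table.index)


def pcoa(distance_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Classical-scaling principal coordinate analysis.

    Double-centers -D^2/2, eigendecomposes, and returns coordinates
    (eigenvectors scaled by sqrt(eigenvalue)) for the positive eigenvalues
    only, plus the full eigenvalue spectrum in descending order so
    negative eigenvalues remain visible to the caller.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(d - d.T).max() > 1e-8:
        raise ValueError("distance matrix asymmetric beyond 1e-8")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(evals).max()))
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    return coords, evals


def pam_cluster(distance_matrix, n_clusters: int) -> tuple[list[int], np.ndarray]:
    """Partitioning Around Medoids with deterministic BUILD + SWAP.

    BUILD greedily seeds medoids (ties to the lowest index); SWAP applies
    the best total-cost-reducing (medoid, non-medoid) exchange until none
    remains. Returns medoid indices and per-point labels (0..k-1 in medoid
    order).
    """
    d = np.asarray(distance_matrix, dtype=float)
    n = d.shape[0]
    if n_clusters <= 0:
        raise ValueError("n_clusters must be positive")
    if n_clusters >= n + 1:
        raise ValueError("n_clusters must be <= number of points")
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < n_clusters:
        cur = d[:, medoids].min(axis=1)
        # gain of adding candidate c = total reduction in point costs
        gains = np.maximum(cur[None, :] - d, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return d[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap, best_new = None, best_cost
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_new - 1e-12:
                    best_new, best_swap = c, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)
            best_cost = best_new
            improved = True
    labels = np.argmin(d[:, medoids], axis=1)
    return medoids, labels


def pearson_similarity(table: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Pearson correlation of relative-abundance profiles.

    A zero-variance sample has undefined correlation with every other
    sample; its off-diagonal entries are reported missing (NaN).
    """
    x = table.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 taxa columns")
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    n = x.shape[0]
    sim = np.full((n, n), np.nan)
    for i in range(n):
        sim[i, i] = 1.0
        for j_ in range(i + 1, n):
            if norms[i] > 0 and norms[j_] > 0:
                sim[i, j_] = sim[j_, i] = float(
                    centered[i] @ centered[j_] / (norms[i] * norms[j_]))
    return pd.DataFrame(sim, index=table.index, columns=table.index)


# ---------------------------------------------------------------------------
# Differential gene calling

@dataclass
class DiffGeneResult:
    gene_id: str
    mean_a: float
    mean_b: float
    log2_fold_change: float
    t_statistic: float
    p_value: float
    flagged: bool


def diff_genes(table_a: pd.DataFrame, table_b: pd.DataFrame,
               log2fc_threshold: float = 2.0,
               pseudocount: float | None = None,
               bh_correct: bool = False) -> list[DiffGeneResult]:
    """Call cohort-differential genes by two-log fold change.

    Inputs are samples x genes matrices of the chosen abundance quantity
    (read frequency by default in the pipeline). log2FC = log2((mean_B +
    c) / (mean_A + c)) with pseudocount c defaulting to half the smallest
    nonzero value across both tables; a gene is flagged iff |log2FC| >=
    ``log2fc_threshold``. A one-tailed pooled t-test in the direction of
    the observed difference is attached (Benjamini-Hochberg adjustment of
    those p-values is available but off by default). Results are sorted by
    |log2FC| descending.
    """
    if list(table_a.columns) != list(table_b.columns):
        raise ValueError("gene columns must match between groups")
    if len(table_a) < 2 or len(table_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if pseudocount is None:
        vals = np.concatenate([table_a.to_numpy().ravel(),
                               table_b.to_numpy().ravel()])
        nz = vals[vals > 0]
        pseudocount = float(nz.min() / 2) if nz.size else 0.5
    logger.info("diff_genes: pseudocount=%g threshold=%g bh_correct=%s",
                pseudocount, log2fc_threshold, bh_correct)
    results = []
    for gene in table_a.columns:
        xa = table_a[gene].to_numpy(dtype=float)
        xb = table_b[gene].to_numpy(dtype=float)
        ma, mb = float(xa.mean()), float(xb.mean())
        if ma == 0.0 and mb == 0.0:
            l2fc = 0.0
        else:
            l2fc = float(np.log2((mb + pseudocount) / (ma + pseudocount)))
        tres = two_sample_t(xb, xa, tails=1)
        results.append(DiffGeneResult(
            gene_id=gene, mean_a=ma, mean_b=mb, log2_fold_change=l2fc,
            t_statistic=tres.statistic, p_value=tres.p_value,
            flagged=abs(l2fc) >= log2fc_threshold))
    if bh_correct:
        ps = np.array([r.p_value for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank, idx in enumerate(order[::-1]):
            running = min(running, ps[idx] * m / (m - rank))
            adj[idx] = running
        for r, q in zip(results, adj):
            r.p_value = float(q)
    results.sort(key=lambda r: (-abs(r.log2_fold_change), r.gene_id))
    return results


def diff_genes_frame(results: list[DiffGeneResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Biplot vectors

def biplot_vectors(coordinates: np.ndarray,
                   abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon arrows: correlation of abundance with the first two
    ordination axes. Zero-variance taxa get a zero arrow, flagged.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape[0] != len(abundance):
        raise ValueError("coordinates and abundances must cover the same samples")
    if coords.shape[1] < 2:
        raise ValueError("need at least two ordination axes")
    rows = []
    for taxon in abundance.columns:
        v = abundance[taxon].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            rows.append({"taxon": taxon, "axis1": 0.0, "axis2": 0.0,
                         "degenerate": True})
            continue
        rows.append({
            "taxon": taxon,
            "axis1": float(np.corrcoef(v, coords[:, 0])[0, 1]),
            "axis2": float(np.corrcoef(v, coords[:, 1])[0, 1]),
            "degenerate": False,
        })
    return pd.DataFrame(rows).set_index("taxon")
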