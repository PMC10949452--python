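"""Population structure: genotype PCA, admixture-model EM with
cross-validated choice of K, and a neighbor-joining tree.

The admixture model assumes each individual's genome is a mixture of K
ancestral populations: genotype g_ij ~ Binomial(ploidy, sum_k q_ik f_kj)
with ancestry fractions Q (rows sum to one) and ancestral allele
frequencies F.  The likelihood is maximised by EM, which is slower than
quasi-Newton schemes but monotonically ascending; cross-validation masks
genotype entries, refits, and scores masked entries by binomial deviance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, DistanceMatrix, OrdinationResult, VariantTable

log = logging.getLogger(__name__)

F_EPS = 1e-6


def genotype_pca(v: VariantTable, n_axes: int = 10) -> OrdinationResult:
    """PCA of the standardized dosage matrix.

    Sites are mean-centered and scaled by sqrt(ploidy * p * (1 - p));
    missing dosages are mean-imputed before decomposition.
    """
    g = v.genotypes.astype(float).T  # samples x sites
    g[v.genotypes.T == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / v.ploidy
    seg = (p > 0) & (p < 1) & np.isfinite(p)
    if not seg.any():
        raise ValueError("no segregating sites")
    g = g[:, seg]
    p = p[seg]
    mu = v.ploidy * p
    sd = np.sqrt(v.ploidy * p * (1 - p))
    x = (g - mu) / sd
    x[np.isnan(x)] = 0.0  # mean imputation in standardized units
    n_axes = min(n_axes, min(x.shape) - (1 if x.shape[0] > 1 else 0)) or 1

    u, svals, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    eig = svals**2 / max(x.shape[0] - 1, 1)
    total = eig.sum()
    coords = u[:, :n_axes] * svals[:n_axes]
    return OrdinationResult(
        coordinates=coords,
        eigenvalues=eig[:n_axes],
        pct_explained=100.0 * eig[:n_axes] / total,
        sample_ids=list(v.sample_ids),
    )


@dataclass
class AdmixtureFit:
    q: np.ndarray
    f: np.ndarray
    loglik_trace: list
    k: int
    seed: int
    converged: bool
    sample_ids: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _admixture_loglik(g, mask, ploidy, q, f) -> float:
    p = np.clip(q @ f, F_EPS, 1 - F_EPS)
    ll = np.where(mask, g * np.log(p) + (ploidy - g) * np.log1p(-p), 0.0)
    return float(ll.sum())


def admixture_em(
    v: VariantTable,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    genotype_mask: np.ndarray | None = None,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    Missing genotypes (and any entries excluded by ``genotype_mask``) are
    dropped from the likelihood rather than imputed.  ``genotype_mask`` is
    a sites x samples boolean array of entries to use (for cross-validation).
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > v.n_samples:
        raise ValueError("K exceeds the number of samples")
    g = v.genotypes.astype(float).T  # samples x sites
    mask = v.genotypes.T != MISSING
    if genotype_mask is not None:
        mask = mask & genotype_mask.T
    g = np.where(mask, g, 0.0)
    n, m = g.shape
    ploidy = float(v.ploidy)

    rng = np.random.default_rng(seed)
    q = rng.dirichlet(np.ones(k), size=n)
    f = np.clip(rng.uniform(0.05, 0.95, size=(k, m)), F_EPS, 1 - F_EPS)

    trace = []
    converged = False
    clamped = 0
    for _ in range(max_iter):
        p = np.clip(q @ f, F_EPS, 1 - F_EPS)  # n x m
        # expected ancestry-of-allele counts
        #   a: derived-allele draws attributed to population k
        #   b: ancestral-allele draws attributed to population k
        ga = np.where(mask, g / p, 0.0)
        gb = np.where(mask, (ploidy - g) / (1 - p), 0.0)
        a = q[:, :, None] * f[None, :, :] * ga[:, None, :]  # n x k x m
        b = q[:, :, None] * (1 - f)[None, :, :] * gb[:, None, :]
        f_num = a.sum(axis=0)
        f_den = (a + b).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = np.where(f_den > 0, f_num / np.maximum(f_den, 1e-300), f)
        nclamp = int(((f_new < F_EPS) | (f_new > 1 - F_EPS)).sum())
        clamped += nclamp
        f = np.clip(f_new, F_EPS, 1 - F_EPS)
        q_num = (a + b).sum(axis=2)
        q = q_num / q_num.sum(axis=1, keepdims=True)

        ll = _admixture_loglik(g, mask, ploidy, q, f)
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    if clamped:
        log.debug("clamped %d allele-frequency updates to [eps, 1-eps]", clamped)
    return AdmixtureFit(
        q=q, f=f, loglik_trace=trace, k=k, seed=seed, converged=converged,
        sample_ids=list(v.sample_ids),
    )


@dataclass
class CVReport:
    errors: dict  # K -> mean masked-entry deviance

    @property
    def best_k(self) -> int:
        return min(sorted(self.errors), key=lambda k: self.errors[k])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.errors.items()), columns=["K", "cv_error"]
        ).to_csv(path, sep="\t", index=False)


def _binomial_deviance(g, phat, ploidy) -> np.ndarray:
    phat = np.clip(phat, F_EPS, 1 - F_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(g > 0, g * np.log(g / (ploidy * phat)), 0.0)
        t2 = np.where(
            g < ploidy,
            (ploidy - g) * np.log((ploidy - g) / (ploidy * (1 - phat))),
            0.0,
        )
    return 2.0 * (t1 + t2)


def cv_error(
    v: VariantTable,
    k_range=(2, 3, 4),
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> CVReport:
    """Entry-masking cross-validation error per K.

    Observed genotype entries are partitioned into ``folds`` folds; each
    fold is masked in turn, the model refit, and masked entries scored by
    mean binomial deviance of the predicted allele frequency.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    observed = v.genotypes != MISSING  # sites x samples
    obs_idx = np.argwhere(observed)
    fold_of = rng.integers(0, folds, size=len(obs_idx))

    errors = {}
    for k in k_range:
        devs = []
        for fold in range(folds):
            mask = np.ones(v.genotypes.shape, dtype=bool)
            held = obs_idx[fold_of == fold]
            mask[held[:, 0], held[:, 1]] = False
            fit = admixture_em(
                v, k, seed=seed + 1000 * fold + k, max_iter=max_iter, tol=tol,
                genotype_mask=mask,
            )
            phat = fit.q @ fit.f  # samples x sites
            g_held = v.genotypes[held[:, 0], held[:, 1]].astype(float)
            p_held = phat[held[:, 1], held[:, 0]]
            devs.append(_binomial_deviance(g_held, p_held, float(v.ploidy)))
        errors[int(k)] = float(np.concatenate(devs).mean())
    return CVReport(errors)


# ------------------------------------------------------------------- NJ tree

def allele_sharing_distance(v: VariantTable) -> DistanceMatrix:
    """1 - proportion of matching dosages over sites called in both samples."""
    g = v.genotypes
    n = v.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (g[:, i] != MISSING) & (g[:, j] != MISSING)
            if ok.sum() == 0:
                dist = 0.0
            else:
                dist = 1.0 - float((g[ok, i] == g[ok, j]).mean())
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(v.sample_ids), d)


def nj_tree(d: DistanceMatrix) -> str:
    """Neighbor-joining tree in newick format with branch lengths."""
    if len(d.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    import skbio

    dm = skbio.DistanceMatrix(d.d, ids=list(d.labels))
    tree = skbio.tree.nj(dm)
    return str(tree).strip()
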