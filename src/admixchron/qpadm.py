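"""qpAdm-style admixture-proportion estimation and projection PCA.

A target population's f4 profile against a panel of "right" (outgroup)
populations is modelled as a convex-free mixture of k source profiles:
with a fixed base right R0, the statistic vector y_j = f4(target, R0; R_j,
R0) over the remaining rights should equal sum_i w_i f4(source_i, R0; R_j,
R0) if the target is a w-mixture of the sources.  Weights are estimated by
generalised least squares under the constraint sum(w) = 1, with the
residual covariance and all standard errors from a weighted delete-one
block jackknife; the model-fit tail probability comes from the chi-square
of the minimised quadratic form with (m-1) - (k-1) degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeDataset, allele_frequencies
from .fstats import BlockPartition, f4


# ----------------------------------------------------------------------
# f4 system
# ----------------------------------------------------------------------

def build_f4_vector(
    ds: GenotypeDataset,
    target: str,
    sources: list[str],
    rights: list[str],
    blocks: BlockPartition | None = None,
    freqs: pd.DataFrame | None = None,
):
    """Assemble the qpAdm f4 system with block-jackknife replicates.

    Returns ``(X, y, X_loo, y_loo, block_weights, n_snps)`` where X is
    k x (m-1), y is (m-1), and the ``_loo`` arrays carry delete-one-block
    copies (trailing axis = block) for covariance estimation.
    """
    _check_roles(target, sources, rights)
    if blocks is None:
        blocks = BlockPartition.contiguous(ds)
    if freqs is None:
        freqs = allele_frequencies(ds)
    r0, others = rights[0], rights[1:]
    k, m1, nb = len(sources), len(others), blocks.n_blocks

    y = np.empty(m1)
    X = np.empty((k, m1))
    y_loo = np.empty((m1, nb))
    X_loo = np.empty((k, m1, nb))
    weights = np.zeros(nb)
    n_snps = 0
    for j, rj in enumerate(others):
        res = f4(ds, target, r0, rj, r0, blocks=blocks, freqs=freqs)
        y[j] = res.estimate
        y_loo[j] = res.leave_one_out()
        weights = np.maximum(weights, res.block_weights)
        n_snps = max(n_snps, res.n_snps)
        for i, src in enumerate(sources):
            res_i = f4(ds, src, r0, rj, r0, blocks=blocks, freqs=freqs)
            X[i, j] = res_i.estimate
            X_loo[i, j] = res_i.leave_one_out()
    return X, y, X_loo, y_loo, weights, n_snps


def _check_roles(target: str, sources: list[str], rights: list[str]) -> None:
    roles = [target, *sources, *rights]
    dup = {p for p in roles if roles.count(p) > 1}
    if dup:
        raise ValueError(f"populations appear in more than one role: {sorted(dup)}")
    if len(rights) < len(sources) + 1:
        raise ValueError(
            f"model not identifiable: {len(rights)} rights for "
            f"{len(sources)} sources (need at least k+1)"
        )


def _jackknife_cov(loo: np.ndarray, full: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted delete-one-block jackknife covariance of a statistic vector.

    ``loo``: (dim, n_blocks) delete-one values; ``full``: (dim,) full-data
    estimate; ``w``: per-block weights.  Matrix extension of the Busing
    variance used in :func:`admixchron.fstats.jackknife`.
    """
    keep = w > 0
    loo = loo[:, keep]
    w = w[keep]
    g = w.size
    n = w.sum()
    h = n / w
    est_j = g * full - (loo * (1.0 - w / n)).sum(axis=1)
    tau = h * full[:, None] - (h - 1.0) * loo
    dev = (tau - est_j[:, None]) / np.sqrt(h - 1.0)
    return (dev @ dev.T) / g


def _constrained_gls(X: np.ndarray, y: np.ndarray, siginv: np.ndarray) -> np.ndarray:
    """argmin_w (y - X^T w)^T Siginv (y - X^T w)  s.t.  sum(w) = 1."""
    k = X.shape[0]
    M = X @ siginv @ X.T
    v = X @ siginv @ y
    ones = np.ones(k)
    Minv_v = np.linalg.solve(M, v)
    Minv_1 = np.linalg.solve(M, ones)
    lam = (1.0 - ones @ Minv_v) / (ones @ Minv_1)
    return Minv_v + lam * Minv_1


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

class QpAdm:
    """Two-or-more-way admixture model for one target population.

    Parameters
    ----------
    ds : GenotypeDataset
    target : str
    sources : list of str
        Candidate ancestry sources (k >= 1).
    rights : list of str
        Outgroup panel (m >= k+1); ``rights[0]`` is the base right of the
        f4 system.
    blocks : BlockPartition, optional
        Defaults to contiguous 0.05-Morgan blocks.
    """

    def __init__(
        self,
        ds: GenotypeDataset,
        target: str,
        sources: list[str],
        rights: list[str],
        blocks: BlockPartition | None = None,
        freqs: pd.DataFrame | None = None,
    ):
        _check_roles(target, sources, rights)
        self.ds = ds
        self.target = target
        self.sources = list(sources)
        self.rights = list(rights)
        self.blocks = blocks if blocks is not None else BlockPartition.contiguous(ds)
        self.freqs = freqs

    @classmethod
    def from_dataframe(
        cls, ds: GenotypeDataset, spec: dict, blocks: BlockPartition | None = None
    ) -> "QpAdm":
        """Build from a config mapping with keys target/sources/rights."""
        return cls(ds, spec["target"], list(spec["sources"]), list(spec["rights"]), blocks)

    def fit(self, ridge_rtol: float = 1e8, n_iter: int = 2) -> "QpAdmResults":
        X, y, X_loo, y_loo, bw, n_snps = build_f4_vector(
            self.ds, self.target, self.sources, self.rights,
            blocks=self.blocks, freqs=self.freqs,
        )
        k, m1 = X.shape
        keep = bw > 0
        if keep.sum() < 2:
            raise ValueError("need at least 2 jackknife blocks with data")

        def regularised_inverse(sigma: np.ndarray) -> np.ndarray:
            if np.linalg.cond(sigma) > ridge_rtol:
                lam = 1e-6 * np.trace(sigma) / sigma.shape[0]
                warnings.warn(
                    f"ill-conditioned residual covariance; adding ridge {lam:.3g}",
                    stacklevel=3,
                )
                sigma = sigma + lam * np.eye(sigma.shape[0])
            try:
                return np.linalg.inv(sigma)
            except np.linalg.LinAlgError as err:
                raise ValueError(
                    "singular residual covariance: add blocks or right populations"
                ) from err

        # iterate: covariance of y, fit, then covariance of the residual
        sigma = _jackknife_cov(y_loo, y, bw)
        siginv = regularised_inverse(sigma)
        if k == 1:
            w = np.ones(1)
        else:
            w = _constrained_gls(X, y, siginv)
        for _ in range(n_iter):
            r_full = y - X.T @ w
            r_loo = y_loo - np.einsum("kjb,k->jb", X_loo, w)
            sigma = _jackknife_cov(r_loo, r_full, bw)
            siginv = regularised_inverse(sigma)
            if k > 1:
                w = _constrained_gls(X, y, siginv)

        resid = y - X.T @ w
        chi2 = float(resid @ siginv @ resid)
        dof = m1 - (k - 1)
        fit_p = float(stats.chi2.sf(chi2, dof))

        # delete-one-block refits for weight covariance
        nb = bw.size
        w_loo = np.full((k, nb), np.nan)
        for b in range(nb):
            if bw[b] <= 0:
                continue
            Xb = X_loo[:, :, b]
            yb = y_loo[:, b]
            if np.isnan(Xb).any() or np.isnan(yb).any():
                continue
            w_loo[:, b] = (
                np.ones(1) if k == 1 else _constrained_gls(Xb, yb, siginv)
            )
        ok = ~np.isnan(w_loo).any(axis=0) & (bw > 0)
        if ok.sum() < 2:
            raise ValueError("too few valid jackknife replicates for weight SEs")
        wcov = _jackknife_cov(w_loo[:, ok], w, bw[ok])
        se = np.sqrt(np.clip(np.diag(wcov), 0.0, None))
        resid_z = resid / np.sqrt(np.clip(np.diag(sigma), 1e-300, None))

        return QpAdmResults(
            model=self,
            weights=w,
            se=se,
            weight_cov=wcov,
            fit_p=fit_p,
            chi2=chi2,
            dof=dof,
            n_snps=n_snps,
            residual_z=resid_z,
            sigma=sigma,
        )


@dataclass
class QpAdmResults:
    """Mixture weights with jackknife uncertainties and model-fit P."""

    model: QpAdm
    weights: np.ndarray
    se: np.ndarray
    weight_cov: np.ndarray
    fit_p: float
    chi2: float
    dof: int
    n_snps: int
    residual_z: np.ndarray
    sigma: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return self.weights

    @property
    def bse(self) -> np.ndarray:
        return self.se

    def _source_index(self, source: str | None) -> int:
        if source is None:
            if len(self.model.sources) != 1:
                raise ValueError("source label required for multi-source fit")
            return 0
        return self.model.sources.index(source)

    def weight(self, source: str | None = None) -> float:
        return float(self.weights[self._source_index(source)])

    def weight_se(self, source: str | None = None) -> float:
        return float(self.se[self._source_index(source)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "target": self.model.target,
                "source": self.model.sources,
                "weight": self.weights,
                "se": self.se,
                "fit_p": self.fit_p,
                "n_snps": self.n_snps,
            }
        )

    def summary(self) -> str:
        lines = [
            f"qpAdm fit: {self.model.target} ~ {' + '.join(self.model.sources)}",
            f"  rights: {', '.join(self.model.rights)}",
            f"  n_snps {self.n_snps}, chi2 {self.chi2:.3f} (dof {self.dof}), "
            f"fit P = {self.fit_p:.4f}",
        ]
        for s, w, e in zip(self.model.sources, self.weights, self.se):
            lines.append(f"  {s:>20s}  {w: .4f} +- {e:.4f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# projection PCA
# ----------------------------------------------------------------------

@dataclass
class PCAProjection:
    """PC axes from reference samples; least-squares projection of the rest."""

    coords: pd.DataFrame  # sample, population, is_reference, PC1..PCn
    explained_variance: np.ndarray
    n_axes: int


def pca_fit_project(
    ds: GenotypeDataset,
    reference_pops: list[str],
    projected_samples: list[str] | None = None,
    n_axes: int = 2,
) -> PCAProjection:
    """PCA with axes defined on reference samples and others projected.

    Axes come from the SVD of the reference genotype matrix after mean
    centring and 1/sqrt(p(1-p)) frequency normalisation per SNP (missing
    entries contribute zero after centring).  Projected samples are placed
    by least squares using only their non-missing sites, the standard
    treatment for sparse ancient samples.
    """
    is_ref = ds.samples["population"].isin(reference_pops).to_numpy()
    n_ref = int(is_ref.sum())
    if n_ref < n_axes:
        raise ValueError(f"{n_ref} reference samples < {n_axes} requested axes")
    if projected_samples is None:
        proj_mask = ~is_ref
    else:
        proj_mask = ds.samples["id"].isin(projected_samples).to_numpy()

    dosage = ds.calls.astype(float) / 2.0
    dosage[ds.calls == -1] = np.nan
    ref = dosage[:, is_ref]
    callrate = (~np.isnan(ref)).sum(axis=1)
    usable = callrate > 0
    if not usable.any():
        raise ValueError("no SNP has any reference call")
    ref = ref[usable]
    p = np.nanmean(ref, axis=1)
    norm = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
    poly = (p > 0) & (p < 1)
    ref, p, norm = ref[poly], p[poly], norm[poly]

    Z = (ref - p[:, None]) / norm[:, None]
    Z = np.nan_to_num(Z, nan=0.0)
    # SVD on samples x snps
    U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
    V = Vt[:n_axes].T  # (snps, axes)
    ref_coords = U[:, :n_axes] * S[:n_axes]
    explained = S[:n_axes] ** 2 / (S**2).sum()

    snp_sel = np.flatnonzero(usable)[poly]
    rows = []
    ref_ids = ds.samples.loc[is_ref, "id"].to_numpy()
    ref_pops_arr = ds.samples.loc[is_ref, "population"].to_numpy()
    for sid, pop, coord in zip(ref_ids, ref_pops_arr, ref_coords):
        rows.append((sid, pop, True, *coord))

    proj_idx = np.flatnonzero(proj_mask)
    for j in proj_idx:
        x = dosage[snp_sel, j]
        obs = ~np.isnan(x)
        if not obs.any():
            coord = np.full(n_axes, np.nan)
        else:
            zx = (x[obs] - p[obs]) / norm[obs]
            coord, *_ = np.linalg.lstsq(V[obs], zx, rcond=None)
        rows.append(
            (ds.samples["id"].iloc[j], ds.samples["population"].iloc[j], False, *coord)
        )

    cols = ["sample", "population", "is_reference"] + [f"PC{i+1}" for i in range(n_axes)]
    return PCAProjection(pd.DataFrame(rows, columns=cols), explained, n_axes)
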