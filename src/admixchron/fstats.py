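"""f4-statistics, weighted block-jackknife errors, affinity regression.

The core quantity is f4(A, B; C, D) = mean over SNPs of
(p_A - p_B)(p_C - p_D): zero when (A,B) and (C,D) are symmetric clades,
systematically nonzero under gene flow.  Standard errors come from a
weighted delete-one-block jackknife over contiguous genomic blocks
(default 0.05 Morgans, the ecosystem convention), with per-block SNP
counts as weights.

Per-statistic SNP filtering follows the "allsnps" convention: each
statistic uses every SNP at which its own four population frequencies are
defined.  Pass ``strict_mask`` to force a common SNP set when exact
cross-statistic arithmetic (e.g. the additivity identity) is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset, allele_frequencies


@dataclass
class BlockPartition:
    """Disjoint contiguous genomic blocks assigning every SNP to one block.

    ``blocks``: DataFrame (chrom, start, end) in Morgans;
    ``variant_block``: block index per variant of the dataset it was built on.
    """

    blocks: pd.DataFrame
    variant_block: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @classmethod
    def contiguous(cls, ds: GenotypeDataset, size_morgans: float = 0.05) -> "BlockPartition":
        """Contiguous blocks of ``size_morgans`` within each chromosome."""
        if size_morgans <= 0:
            raise ValueError("block size must be positive")
        chrom = ds.variants["chrom"].to_numpy()
        gpos = ds.variants["gpos"].to_numpy()
        assign = np.empty(len(chrom), dtype=np.int64)
        rows = []
        offset = 0
        for c in dict.fromkeys(chrom):
            sel = chrom == c
            g = gpos[sel]
            local = np.floor((g - g.min()) / size_morgans).astype(np.int64)
            # renumber to the occupied blocks only
            uniq, local = np.unique(local, return_inverse=True)
            assign[sel] = local + offset
            for u in uniq:
                lo = g.min() + u * size_morgans
                rows.append((c, lo, lo + size_morgans))
            offset += uniq.size
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), assign)

    @classmethod
    def per_chromosome(cls, ds: GenotypeDataset) -> "BlockPartition":
        """One block per chromosome (used by the dating module's jackknife)."""
        chrom = ds.variants["chrom"].to_numpy()
        order = list(dict.fromkeys(chrom))
        index = {c: i for i, c in enumerate(order)}
        assign = np.array([index[c] for c in chrom], dtype=np.int64)
        gpos = ds.variants["gpos"].to_numpy()
        rows = [
            (c, gpos[chrom == c].min(), gpos[chrom == c].max()) for c in order
        ]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), assign)


@dataclass
class F4Result:
    """An f4 estimate with its jackknife machinery retained."""

    populations: tuple[str, str, str, str]
    estimate: float
    block_estimates: np.ndarray
    block_weights: np.ndarray
    se: float
    z: float
    n_snps: int

    @property
    def n_blocks(self) -> int:
        return int(np.count_nonzero(self.block_weights))

    def leave_one_out(self) -> np.ndarray:
        """Delete-one-block estimates (for downstream covariance work)."""
        w = self.block_weights
        tot_w = w.sum()
        tot = (w * self.block_estimates).sum()
        with np.errstate(invalid="ignore"):
            out = (tot - w * self.block_estimates) / (tot_w - w)
        out[w >= tot_w] = np.nan
        return out

    def row(self) -> dict:
        a, b, c, d = self.populations
        return {
            "A": a, "B": b, "C": c, "D": d,
            "estimate": self.estimate, "se": self.se, "z": self.z,
            "n_snps": self.n_snps, "n_blocks": self.n_blocks,
        }


# ----------------------------------------------------------------------
# jackknife
# ----------------------------------------------------------------------

def jackknife(block_estimates, block_weights) -> tuple[float, float]:
    """Weighted delete-one-block jackknife mean and standard error.

    Uses the Busing weighted-jackknife variance with per-block weights
    (SNP counts); with equal weights it reduces to the textbook delete-one
    jackknife.  Zero-weight blocks are dropped.  Requires at least two
    blocks with positive weight.
    """
    theta = np.asarray(block_estimates, dtype=float)
    w = np.asarray(block_weights, dtype=float)
    if theta.shape != w.shape:
        raise ValueError("block estimates and weights differ in length")
    keep = w > 0
    theta, w = theta[keep], w[keep]
    g = theta.size
    if g < 2:
        raise ValueError("jackknife needs at least 2 blocks with positive weight")
    n = w.sum()
    est = float((w * theta).sum() / n)
    loo = (n * est - w * theta) / (n - w)  # delete-one-block estimates
    h = n / w
    est_j = g * est - ((1.0 - w / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = float(np.sum((tau - est_j) ** 2 / (h - 1.0)) / g)
    return est, float(np.sqrt(max(var, 0.0)))


def jackknife_from_loo(full: float, loo, weights) -> float:
    """Weighted-jackknife SE from precomputed delete-one-block estimates.

    Same Busing variance as :func:`jackknife`, but taking the leave-one-out
    re-estimates directly — needed when the statistic is a whole re-fit (a
    regression, a decay fit) rather than a weighted mean of block values.
    """
    loo = np.asarray(loo, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = (w > 0) & ~np.isnan(loo)
    loo, w = loo[keep], w[keep]
    g = loo.size
    if g < 2:
        raise ValueError("jackknife needs at least 2 usable replicates")
    n = w.sum()
    h = n / w
    est_j = g * full - ((1.0 - w / n) * loo).sum()
    tau = h * full - (h - 1.0) * loo
    var = float(np.sum((tau - est_j) ** 2 / (h - 1.0)) / g)
    return float(np.sqrt(max(var, 0.0)))


def _z_of(estimate: float, se: float) -> float:
    if se > 0:
        return estimate / se
    return 0.0 if estimate == 0 else float(np.sign(estimate)) * np.inf


# ----------------------------------------------------------------------
# f4
# ----------------------------------------------------------------------

def f4(
    ds: GenotypeDataset,
    A: str,
    B: str,
    C: str,
    D: str,
    blocks: BlockPartition | None = None,
    freqs: pd.DataFrame | None = None,
    strict_mask: np.ndarray | None = None,
) -> F4Result:
    """f4(A, B; C, D) with weighted block-jackknife standard error.

    ``freqs`` (from :func:`admixchron.io.allele_frequencies`) may be passed
    to amortise the frequency computation across many statistics; it must be
    aligned with ``ds.variants``.
    """
    if blocks is None:
        blocks = BlockPartition.contiguous(ds)
    if freqs is None:
        freqs = allele_frequencies(ds)
    for pop in (A, B, C, D):
        if pop not in freqs.columns.get_level_values(0):
            raise KeyError(f"population {pop!r} has no frequencies")
    pA, pB, pC, pD = (freqs[(p, "freq")].to_numpy() for p in (A, B, C, D))
    usable = ~(np.isnan(pA) | np.isnan(pB) | np.isnan(pC) | np.isnan(pD))
    if strict_mask is not None:
        usable &= np.asarray(strict_mask, dtype=bool)
    if not usable.any():
        raise ValueError(f"no usable SNPs for f4({A},{B};{C},{D})")
    for pop, arr in ((A, pA), (B, pB), (C, pC), (D, pD)):
        if np.isnan(arr[usable]).all():
            raise ValueError(f"population {pop!r} all-missing on analysis SNPs")

    prod = (pA - pB) * (pC - pD)
    bidx = blocks.variant_block
    nb = blocks.n_blocks
    sums = np.bincount(bidx[usable], weights=prod[usable], minlength=nb)
    counts = np.bincount(bidx[usable], minlength=nb)
    with np.errstate(invalid="ignore"):
        block_est = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    est, se = jackknife(block_est, counts)
    return F4Result(
        populations=(A, B, C, D),
        estimate=est,
        block_estimates=block_est,
        block_weights=counts.astype(float),
        se=se,
        z=_z_of(est, se),
        n_snps=int(usable.sum()),
    )


def symmetry_scan(
    ds: GenotypeDataset,
    targets: list[str],
    baseline: str,
    popC: str,
    popD: str,
    blocks: BlockPartition | None = None,
    freqs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """f4(target, baseline; popC, popD) for each target; raw Z, no correction.

    A significantly nonzero Z marks asymmetry between target and baseline in
    their affinity to popC vs popD (e.g. excess Papuan ancestry relative to
    an unadmixed East Asian baseline).
    """
    if blocks is None:
        blocks = BlockPartition.contiguous(ds)
    if freqs is None:
        freqs = allele_frequencies(ds)
    rows = []
    for target in targets:
        res = f4(ds, target, baseline, popC, popD, blocks=blocks, freqs=freqs)
        rows.append(res.row())
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# inverse-variance-weighted f4 regression
# ----------------------------------------------------------------------

class F4Regression:
    """Inverse-variance-weighted least squares on paired f4 statistics.

    Each point is an (x +- sx, y +- sy) pair of f4 estimates; the fit solves
    weighted least squares with weights 1/sy^2.  When block-level leave-one-out
    replicates of x and y are supplied (or the model is built from
    :class:`F4Result` pairs), per-point residual standard errors come from a
    delete-one-block jackknife that re-derives the points and re-fits the
    line in every replicate.
    """

    def __init__(self, x, y, sy, sx=None, x_loo=None, y_loo=None, block_weights=None):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.sy = np.asarray(sy, dtype=float)
        self.sx = None if sx is None else np.asarray(sx, dtype=float)
        if self.x.size < 3:
            raise ValueError("need at least 3 points")
        if np.allclose(self.x, self.x[0]):
            raise ValueError("degenerate regression: all x equal")
        if (self.sy <= 0).any():
            raise ValueError("y standard errors must be positive")
        self.x_loo = None if x_loo is None else np.asarray(x_loo, dtype=float)
        self.y_loo = None if y_loo is None else np.asarray(y_loo, dtype=float)
        self.block_weights = (
            None if block_weights is None else np.asarray(block_weights, dtype=float)
        )

    @classmethod
    def from_f4_results(cls, x_results: list[F4Result], y_results: list[F4Result]):
        if len(x_results) != len(y_results):
            raise ValueError("x and y statistic lists differ in length")
        x = np.array([r.estimate for r in x_results])
        y = np.array([r.estimate for r in y_results])
        sx = np.array([r.se for r in x_results])
        sy = np.array([r.se for r in y_results])
        x_loo = np.vstack([r.leave_one_out() for r in x_results])
        y_loo = np.vstack([r.leave_one_out() for r in y_results])
        bw = np.mean(
            [r.block_weights for r in x_results + y_results], axis=0
        )
        return cls(x, y, sy, sx=sx, x_loo=x_loo, y_loo=y_loo, block_weights=bw)

    @staticmethod
    def _wls(x, y, w) -> tuple[float, float]:
        W = w.sum()
        xm = (w * x).sum() / W
        ym = (w * y).sum() / W
        sxx = (w * (x - xm) ** 2).sum()
        slope = (w * (x - xm) * (y - ym)).sum() / sxx
        return slope, ym - slope * xm

    def fit(self) -> "F4RegressionResults":
        w = 1.0 / self.sy**2
        slope, intercept = self._wls(self.x, self.y, w)
        resid = self.y - (intercept + slope * self.x)

        if self.x_loo is not None and self.y_loo is not None:
            nb = self.x_loo.shape[1]
            bw = (
                self.block_weights
                if self.block_weights is not None
                else np.ones(nb)
            )
            resid_reps = np.empty((self.x.size, nb))
            for b in range(nb):
                xb = self.x_loo[:, b]
                yb = self.y_loo[:, b]
                if np.isnan(xb).any() or np.isnan(yb).any():
                    resid_reps[:, b] = np.nan
                    continue
                sb, ib = self._wls(xb, yb, w)
                resid_reps[:, b] = yb - (ib + sb * xb)
            resid_se = np.empty(self.x.size)
            for i in range(self.x.size):
                resid_se[i] = jackknife_from_loo(resid[i], resid_reps[i], bw)
        else:
            resid_se = self.sy.copy()

        with np.errstate(divide="ignore", invalid="ignore"):
            resid_z = np.where(resid_se > 0, resid / resid_se, 0.0)
        return F4RegressionResults(self, slope, intercept, resid, resid_se, resid_z, w)


@dataclass
class F4RegressionResults:
    model: F4Regression
    slope: float
    intercept: float
    residuals: np.ndarray
    residual_se: np.ndarray
    residual_z: np.ndarray
    weights: np.ndarray

    @property
    def params(self) -> np.ndarray:
        return np.array([self.intercept, self.slope])

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        lines = [
            "Inverse-variance-weighted f4 regression",
            f"  slope     {self.slope: .6g}",
            f"  intercept {self.intercept: .6g}",
            f"  points    {self.residuals.size}",
            "  point   residual      resid_SE   Z",
        ]
        for i, (r, s, z) in enumerate(
            zip(self.residuals, self.residual_se, self.residual_z)
        ):
            lines.append(f"  {i:5d}  {r: .4e}  {s: .3e}  {z: .2f}")
        return "\n".join(lines)


# ----------------------------------------------------------------------
# sex bias
# ----------------------------------------------------------------------

def _weight_and_se(fit, source: str | None) -> tuple[float, float]:
    if isinstance(fit, tuple):
        return float(fit[0]), float(fit[1])
    return float(fit.weight(source)), float(fit.weight_se(source))


def sex_bias_z(fit_autosome, fit_X, source: str | None = None) -> float:
    """Autosome-vs-X ancestry-difference Z score.

    Z = (alpha_auto - alpha_X) / sqrt(se_auto^2 + se_X^2); positive Z means
    the ``source`` ancestry (e.g. Papuan) is higher on the autosomes than on
    the X, the signature of male-biased admixture from that source.  Fits
    may be :class:`~admixchron.qpadm.QpAdmResults` or plain ``(alpha, se)``
    tuples.
    """
    a_auto, se_auto = _weight_and_se(fit_autosome, source)
    a_x, se_x = _weight_and_se(fit_X, source)
    denom = se_auto**2 + se_x**2
    if denom == 0:
        raise ValueError("both fits have zero standard error")
    return float((a_auto - a_x) / np.sqrt(denom))


def f4_table(results: list[F4Result]) -> pd.DataFrame:
    """One row per statistic: A, B, C, D, estimate, se, z, n_snps, n_blocks."""
    return pd.DataFrame([r.row() for r in results])
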