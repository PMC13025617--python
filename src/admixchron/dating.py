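"""Admixture dating from the decay of ancestry covariance with distance.

In a population formed by a single admixture pulse n generations ago,
recombination has broken the source chromosomes into tracts of expected
length 1/n Morgans, so the covariance of local ancestry between two loci a
genetic distance d apart decays as alpha(1-alpha) exp(-n d).  Local
ancestry is not observed directly in genotype data; instead each SNP is
weighted by the source allele-frequency difference w_s = p1_s - p2_s, and
the weighted covariance of genotype residuals around the mixture mean
inherits the exp(-n d) decay.  Fitting A exp(-n d) + c to the binned curve
estimates n; a delete-one-chromosome jackknife gives its standard error.

This is the same estimand as the DATES/ALDER family of methods; the
normalisation here is this package's own (documented in the methods note)
and is expected to agree in the decay rate, not the amplitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .io import MISSING, GenotypeDataset, allele_frequencies
from .fstats import jackknife_from_loo


@dataclass
class DecayCurve:
    """Binned weighted ancestry covariance vs genetic distance.

    Per-chromosome numerator/denominator sums are retained so that
    leave-one-chromosome curves (for the jackknife) are exact and cheap.
    """

    bin_centres: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    per_chrom_num: dict[str, np.ndarray] = field(repr=False)
    per_chrom_den: dict[str, np.ndarray] = field(repr=False)
    per_chrom_pairs: dict[str, np.ndarray] = field(repr=False)
    binsize: float
    maxdis: float
    alpha_used: float

    @property
    def chromosomes(self) -> list[str]:
        return list(self.per_chrom_num)

    def leave_one_out(self, chrom: str) -> np.ndarray:
        num = sum(v for c, v in self.per_chrom_num.items() if c != chrom)
        den = sum(v for c, v in self.per_chrom_den.items() if c != chrom)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)

    def chrom_weight(self, chrom: str) -> float:
        return float(self.per_chrom_den[chrom].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_centre_M": self.bin_centres,
                "value": self.values,
                "n_pairs": self.n_pairs,
            }
        )


def _estimate_alpha(
    target_mean: np.ndarray, p1: np.ndarray, p2: np.ndarray
) -> float:
    """Least-squares mixture fraction of source2 from single-SNP signals.

    Solves target_mean ~= (1-alpha) p1 + alpha p2 over SNPs.
    """
    d = p2 - p1
    ok = ~(np.isnan(target_mean) | np.isnan(d))
    denom = float((d[ok] ** 2).sum())
    if denom == 0:
        raise ValueError("sources have identical frequencies everywhere")
    return float(((target_mean - p1)[ok] * d[ok]).sum() / denom)


def ancestry_covariance_curve(
    ds: GenotypeDataset,
    target_samples: list[str],
    source1: str,
    source2: str,
    binsize: float = 0.001,
    maxdis: float = 1.0,
    alpha: float | None = None,
    freqs: pd.DataFrame | None = None,
) -> DecayCurve:
    """Weighted ancestry-covariance decay curve for a target sample group.

    Distances are in Morgans throughout (``maxdis`` default 1.0 Morgans —
    deliberately generous so long admixture LD from recent pulses is kept).
    Per SNP the weight is w_s = p1_s - p2_s; per individual the residual is
    x_is = g_is/2 - mu_s with mu_s the alpha-mixture mean frequency (alpha
    re-estimated from the data unless supplied).  Same-chromosome SNP pairs
    are binned by distance; each bin averages w_s w_t <x_s x_t> over
    individuals, normalised by the summed |w_s w_t|.  Missing calls drop an
    individual from a pair.
    """
    if binsize <= 0 or maxdis <= binsize:
        raise ValueError("need 0 < binsize < maxdis")
    if not target_samples:
        raise ValueError("at least one target sample required")
    if freqs is None:
        freqs = allele_frequencies(ds)
    p1 = freqs[(source1, "freq")].to_numpy()
    p2 = freqs[(source2, "freq")].to_numpy()
    tidx = np.array([list(ds.samples["id"]).index(s) for s in target_samples])

    g = ds.calls[:, tidx].astype(float) / 2.0
    g[ds.calls[:, tidx] == MISSING] = np.nan
    usable = ~(np.isnan(p1) | np.isnan(p2))
    n_called = (~np.isnan(g)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        target_mean = np.where(
            n_called > 0, np.nansum(g, axis=1) / np.maximum(n_called, 1), np.nan
        )
    if alpha is None:
        alpha = _estimate_alpha(target_mean[usable], p1[usable], p2[usable])
    mu = (1.0 - alpha) * p1 + alpha * p2
    w = p1 - p2

    x = g - mu[:, None]
    called = ~np.isnan(x)
    x = np.nan_to_num(x, nan=0.0)

    chrom_arr = ds.variants["chrom"].to_numpy()
    gpos = ds.variants["gpos"].to_numpy()
    n_bins = int(np.ceil(maxdis / binsize))
    centres = (np.arange(n_bins) + 0.5) * binsize

    per_num: dict[str, np.ndarray] = {}
    per_den: dict[str, np.ndarray] = {}
    per_pairs: dict[str, np.ndarray] = {}
    any_pairs = False
    for chrom in dict.fromkeys(chrom_arr):
        sel = np.flatnonzero((chrom_arr == chrom) & usable)
        if sel.size < 2:
            continue
        gp = gpos[sel]
        xs = x[sel]
        cs = called[sel].astype(np.float64)
        ws = w[sel]
        # sum over individuals of x_s x_t and count of doubly-called pairs
        S = xs @ xs.T
        N = cs @ cs.T
        iu, ju = np.triu_indices(sel.size, k=1)
        d = gp[ju] - gp[iu]
        inrange = (d > 0) & (d <= maxdis)
        iu, ju, d = iu[inrange], ju[inrange], d[inrange]
        bidx = np.minimum((d / binsize).astype(np.int64), n_bins - 1)
        npair = N[iu, ju]
        has = npair > 0
        wprod = ws[iu] * ws[ju]
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_prod = np.where(has, S[iu, ju] / np.maximum(npair, 1.0), 0.0)
        num = np.bincount(bidx, weights=wprod * mean_prod, minlength=n_bins)
        den = np.bincount(
            bidx, weights=np.abs(wprod) * has, minlength=n_bins
        )
        cnt = np.bincount(bidx[has], minlength=n_bins)
        per_num[str(chrom)] = num
        per_den[str(chrom)] = den
        per_pairs[str(chrom)] = cnt
        any_pairs = any_pairs or has.any()
    if not any_pairs:
        raise ValueError("no same-chromosome SNP pairs within maxdis")

    num = sum(per_num.values())
    den = sum(per_den.values())
    pairs = sum(per_pairs.values())
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return DecayCurve(
        centres, values, pairs, per_num, per_den, per_pairs,
        binsize, maxdis, float(alpha),
    )


# ----------------------------------------------------------------------
# exponential fit
# ----------------------------------------------------------------------

def _fit_exp_single(
    d: np.ndarray, v: np.ndarray, fit_affine: bool
) -> tuple[float, float, float, float]:
    """Best (n, A, c, sse) for v ~ A exp(-n d) + c by grid + local refinement."""

    def linfit(n: float) -> tuple[float, float, float]:
        e = np.exp(-n * d)
        if fit_affine:
            M = np.column_stack([e, np.ones_like(e)])
            coef, *_ = np.linalg.lstsq(M, v, rcond=None)
            A, c = float(coef[0]), float(coef[1])
        else:
            A = float((e * v).sum() / (e * e).sum())
            c = 0.0
        resid = v - (A * e + c)
        return A, c, float(resid @ resid)

    grid = np.geomspace(0.5, 500.0, 120)
    sses = np.array([linfit(n)[2] for n in grid])
    best = int(np.argmin(sses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda n: linfit(n)[2], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    n_hat = float(res.x)
    A, c, sse = linfit(n_hat)
    return n_hat, A, c, sse


@dataclass
class DecayResults:
    """Fitted decay parameters with chromosome-jackknife uncertainty."""

    n_generations: float
    amplitude: float
    affine: float
    se_generations: float
    mindis: float
    maxdis: float
    binsize: float
    loo_n: dict[str, float]
    curve: DecayCurve = field(repr=False)
    method: str = "grid+bounded-refine"

    def ci95(self) -> tuple[int, int]:
        """(upper, lower) integer generation bounds, 1.96-sigma."""
        from .chronology import generations_ci

        return generations_ci(self.n_generations, self.se_generations)

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return self.amplitude * np.exp(-self.n_generations * d) + self.affine

    def summary(self) -> str:
        up, lo = self.ci95()
        return (
            "Admixture-LD decay fit\n"
            f"  n = {self.n_generations:.1f} +- {self.se_generations:.1f} "
            f"generations (95% CI {up}-{lo})\n"
            f"  amplitude {self.amplitude:.3e}, affine {self.affine:.3e}\n"
            f"  fit range [{self.mindis:g}, {self.maxdis:g}] M, "
            f"binsize {self.binsize:g} M, "
            f"{len(self.loo_n)} jackknife chromosomes"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_generations": self.n_generations,
                    "se_generations": self.se_generations,
                    "amplitude": self.amplitude,
                    "affine": self.affine,
                    "mindis": self.mindis,
                    "maxdis": self.maxdis,
                    "binsize": self.binsize,
                    "alpha_used": self.curve.alpha_used,
                },
                indent=2,
            )
        )


def fit_exponential(
    curve: DecayCurve, mindis: float = 0.005, fit_affine: bool = True
) -> DecayResults:
    """Fit A exp(-n d) + c to a decay curve over [mindis, maxdis].

    Near-zero bins (default below 0.005 M) are discarded: they carry
    background LD unrelated to admixture.  The SE of n comes from a
    weighted delete-one-chromosome jackknife of the complete fit.
    """
    sel = (curve.bin_centres >= mindis) & ~np.isnan(curve.values)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 usable bins in the fit range")
    d = curve.bin_centres[sel]
    v = curve.values[sel]
    n_hat, A, c, _ = _fit_exp_single(d, v, fit_affine)
    if A <= 1e-9 * max(np.abs(v).max(), 1e-300):
        raise ValueError("no decay signal: fitted amplitude is non-positive")

    loo_n: dict[str, float] = {}
    weights = []
    for chrom in curve.chromosomes:
        vv = curve.leave_one_out(chrom)[sel]
        ok = ~np.isnan(vv)
        if ok.sum() < 5:
            continue
        nj, Aj, _, _ = _fit_exp_single(d[ok], vv[ok], fit_affine)
        loo_n[chrom] = nj
        weights.append(curve.chrom_weight(chrom))
    if len(loo_n) < 2:
        raise ValueError("need at least 2 chromosomes for the jackknife")
    reps = np.array(list(loo_n.values()))
    w = np.array(weights)
    se = jackknife_from_loo(n_hat, reps, w)
    return DecayResults(
        n_generations=n_hat, amplitude=A, affine=c, se_generations=se,
        mindis=mindis, maxdis=curve.maxdis, binsize=curve.binsize,
        loo_n=loo_n, curve=curve,
    )


# ----------------------------------------------------------------------
# model wrapper and target merging
# ----------------------------------------------------------------------

class AdmixtureDecay:
    """Date a single-pulse admixture from ancestry-LD decay.

    Parameters mirror :func:`ancestry_covariance_curve`; ``fit`` adds the
    exponential model and its jackknife SE.  ``alpha`` overrides the
    internally estimated mixture fraction (e.g. with a qpAdm weight).
    """

    def __init__(
        self,
        ds: GenotypeDataset,
        target_samples: list[str],
        source1: str,
        source2: str,
        binsize: float = 0.001,
        maxdis: float = 1.0,
        alpha: float | None = None,
        freqs: pd.DataFrame | None = None,
    ):
        self.ds = ds
        self.target_samples = list(target_samples)
        self.source1 = source1
        self.source2 = source2
        self.binsize = binsize
        self.maxdis = maxdis
        self.alpha = alpha
        self.freqs = freqs
        self._curve: DecayCurve | None = None

    def curve(self) -> DecayCurve:
        if self._curve is None:
            self._curve = ancestry_covariance_curve(
                self.ds, self.target_samples, self.source1, self.source2,
                binsize=self.binsize, maxdis=self.maxdis, alpha=self.alpha,
                freqs=self.freqs,
            )
        return self._curve

    def fit(self, mindis: float = 0.005, fit_affine: bool = True) -> DecayResults:
        return fit_exponential(self.curve(), mindis=mindis, fit_affine=fit_affine)


def merge_targets(
    ds: GenotypeDataset, sample_groups: dict[str, list[str]]
) -> dict[str, list[str]]:
    """Validate named target groups for joint decay curves.

    Merging individuals of similar date multiplies the usable pair count
    (every individual contributes pairs at every distance) without altering
    any genotype; returns the validated group mapping.
    """
    known = set(ds.samples["id"])
    out = {}
    for name, members in sample_groups.items():
        if not members:
            raise ValueError(f"target group {name!r} is empty")
        unknown = set(members) - known
        if unknown:
            raise KeyError(f"group {name!r}: unknown samples {sorted(unknown)[:5]}")
        out[name] = list(members)
    return out


def plot_decay(results: DecayResults, ax=None):
    """Decay curve with the fitted exponential overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    c = results.curve
    sel = c.bin_centres >= results.mindis
    ax.plot(c.bin_centres[sel] * 100, c.values[sel], ".", ms=3, alpha=0.6,
            label="binned ancestry covariance")
    dd = np.linspace(results.mindis, results.maxdis, 400)
    ax.plot(dd * 100, results.predict(dd), "r-", lw=1.5,
            label=f"fit: n = {results.n_generations:.1f} "
                  f"± {results.se_generations:.1f} gen")
    ax.set_xlabel("genetic distance (cM)")
    ax.set_ylabel("weighted ancestry covariance")
    ax.legend(frameon=False)
    return ax
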