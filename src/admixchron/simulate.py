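"""Synthetic admixed cohorts with known truth, and toy calibration curves.

The generator emulates the study design the downstream statistics assume:
two source populations (an East Asian-like and a Papuan-like lineage)
diverged by pure drift from a shared ancestor (Balding-Nichols model), an
admixed cohort formed by a single pulse ``admixture_generations`` ago with
Papuan fraction ``alpha_autosome`` (``alpha_X`` on the X, modelling
male-biased Papuan ancestry), pseudo-haploid genotype sampling with uniform
missingness, and a drifted outgroup.  Ancestry along each haploid chromosome
is a Markov tract process: Poisson breakpoints at rate n per Morgan with the
ancestry redrawn independently at each breakpoint, which yields the
exponentially decaying ancestry covariance alpha(1-alpha)exp(-n d) that the
dating module fits.

Truth objects (tract tables, realised ancestry dosages, the generating
parameters) are returned alongside every dataset; pipeline stages never see
them, only tests do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, write_eigenstrat

#: population labels used throughout the synthetic suite
EAST_ASIAN = "EastAsian"
PAPUAN = "Papuan"
ADMIXED = "Admixed"
#: default outgroup/right panel (see drift defaults below)
OUTGROUPS = ("Outgroup0", "OutEastAsian", "OutPapuan", "Outgroup1")


def _default_drift() -> dict[str, float]:
    # sources plus a right panel: two deep outgroups and one sister group per
    # source lineage, so the qpAdm f4 system has full rank
    return {
        EAST_ASIAN: 0.10,
        PAPUAN: 0.12,
        "Outgroup0": 0.25,
        "OutEastAsian": 0.08,
        "OutPapuan": 0.08,
        "Outgroup1": 0.30,
    }


def _default_related() -> dict[str, str]:
    return {"OutEastAsian": EAST_ASIAN, "OutPapuan": PAPUAN}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions.

    ``alpha_autosome``/``alpha_X`` are Papuan ancestry fractions;
    ``admixture_generations`` the single-pulse admixture time in generations;
    ``chrom_length`` in Morgans.
    """

    n_snps_per_chrom: int = 2000
    n_chroms: int = 22
    chrom_length: float = 1.0
    drift_F: dict[str, float] = field(default_factory=_default_drift)
    related_to: dict[str, str] = field(default_factory=_default_related)
    alpha_autosome: float = 0.40
    alpha_X: float = 0.30
    admixture_generations: float = 30.0
    n_admixed: int = 20
    n_source1: int = 10
    n_source2: int = 10
    n_outgroup: int = 10
    missing_rate: float = 0.05
    pseudo_haploid: bool = True
    include_x: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha_autosome", "alpha_X", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "missing_rate" and v >= 1.0):
                raise ValueError(f"{name}={v} out of range")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if self.admixture_generations <= 0:
            raise ValueError("admixture_generations must be positive")
        for pop, F in self.drift_F.items():
            if not 0.0 < F < 1.0:
                raise ValueError(f"drift F for {pop} must be in (0,1), got {F}")
        for child, parent in self.related_to.items():
            if child in (EAST_ASIAN, PAPUAN):
                raise ValueError("source populations cannot be nested")
            if parent not in self.drift_F or child not in self.drift_F:
                raise ValueError(f"related_to entry {child}->{parent} not in drift_F")

    @property
    def chromosomes(self) -> list[str]:
        chroms = [str(c) for c in range(1, self.n_chroms + 1)]
        if self.include_x:
            chroms.append("X")
        return chroms


# ----------------------------------------------------------------------
# allele frequencies under drift
# ----------------------------------------------------------------------

def _variant_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sorted SNP positions per chromosome; 1 cM/Mb physical surrogate."""
    rows = []
    for chrom in cfg.chromosomes:
        g = np.sort(rng.uniform(0.0, cfg.chrom_length, cfg.n_snps_per_chrom))
        # strictly increasing integer bp positions from the genetic positions
        pos = np.unique(np.round(g * 1e8).astype(np.int64))
        while pos.size < g.size:  # collisions after rounding: respace
            g = np.sort(rng.uniform(0.0, cfg.chrom_length, cfg.n_snps_per_chrom))
            pos = np.unique(np.round(g * 1e8).astype(np.int64))
        for i, (gp, pp) in enumerate(zip(g, pos)):
            rows.append((f"snp_{chrom}_{i}", chrom, gp, int(pp) + 1, "A", "C"))
    return pd.DataFrame(rows, columns=["id", "chrom", "gpos", "pos", "ref", "alt"])


def simulate_source_frequencies(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balding-Nichols population frequencies for every configured population.

    Returns ``(variants, freqs)``: the variant map and a DataFrame with one
    column per population plus ``ancestral`` (the shared ancestral frequency
    q ~ Uniform(0.05, 0.95)); each population's frequency is drawn from
    Beta(q(1-F)/F, (1-q)(1-F)/F) with its drift parameter F.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    variants = _variant_map(cfg, rng)
    n = len(variants)
    q = rng.uniform(0.05, 0.95, n)
    freqs = {"ancestral": q}

    def draw(base: np.ndarray, F: float) -> np.ndarray:
        scale = (1.0 - F) / F
        # clip away exact fixation so the Beta parameters stay positive
        b = np.clip(base, 1e-6, 1.0 - 1e-6)
        return rng.beta(b * scale, (1.0 - b) * scale)

    parents = [p for p in sorted(cfg.drift_F) if p not in cfg.related_to]
    for pop in parents:
        freqs[pop] = draw(q, cfg.drift_F[pop])
    for pop in sorted(cfg.related_to):
        freqs[pop] = draw(freqs[cfg.related_to[pop]], cfg.drift_F[pop])
    return variants, pd.DataFrame(freqs)


# ----------------------------------------------------------------------
# ancestry tracts
# ----------------------------------------------------------------------

def simulate_ancestry_tracts(
    cfg: SimConfig,
    n_haplotypes: int = 1,
    alpha: float | None = None,
    chromosomes: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-pulse ancestry tracts for ``n_haplotypes`` haploid genomes.

    Breakpoints are Poisson at rate ``admixture_generations`` per Morgan;
    the ancestry of each segment is drawn i.i.d. (Papuan with probability
    alpha).  Returns a DataFrame (haplotype, chrom, start, end, ancestry)
    whose tracts tile [0, chrom_length] on every chromosome.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if alpha is None:
        alpha = cfg.alpha_autosome
    if chromosomes is None:
        chromosomes = [str(c) for c in range(1, cfg.n_chroms + 1)]
    n_gen = cfg.admixture_generations
    L = cfg.chrom_length
    rows = []
    for hap in range(n_haplotypes):
        for chrom in chromosomes:
            k = rng.poisson(n_gen * L)
            cuts = np.sort(rng.uniform(0.0, L, k))
            bounds = np.concatenate([[0.0], cuts, [L]])
            anc = rng.random(k + 1) < alpha
            for s, e, a in zip(bounds[:-1], bounds[1:], anc):
                rows.append((hap, chrom, s, e, PAPUAN if a else EAST_ASIAN))
    return pd.DataFrame(rows, columns=["haplotype", "chrom", "start", "end", "ancestry"])


def _hap_ancestry_at(
    gpos: np.ndarray, L: float, alpha: float, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[float, float, bool]]]:
    """Ancestry indicator (True = Papuan) at SNP positions for one haplotype."""
    k = rng.poisson(rate * L)
    cuts = np.sort(rng.uniform(0.0, L, k))
    anc = rng.random(k + 1) < alpha
    seg = np.searchsorted(cuts, gpos, side="right")
    bounds = np.concatenate([[0.0], cuts, [L]])
    tracts = [(bounds[i], bounds[i + 1], bool(anc[i])) for i in range(k + 1)]
    return anc[seg], tracts


# ----------------------------------------------------------------------
# cohort
# ----------------------------------------------------------------------

def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeDataset, dict]:
    """Generate the full synthetic dataset plus its truth record.

    The dataset holds the admixed cohort, both unadmixed sources and the
    outgroup.  Admixed diploids carry two independent haploid tract sets per
    chromosome (one on the male X); genotypes are drawn per site from the
    local ancestry's source frequency, then pseudo-haploid collapsed (one
    allele kept uniformly at random per site) if configured, then masked
    i.i.d. at ``missing_rate``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    variants, freqs = simulate_source_frequencies(cfg, rng)
    chrom_arr = variants["chrom"].to_numpy()
    gpos_arr = variants["gpos"].to_numpy()
    n_var = len(variants)

    outgroup_pops = [p for p in sorted(cfg.drift_F) if p not in (EAST_ASIAN, PAPUAN)]
    samples = []
    for i in range(cfg.n_admixed):
        samples.append((f"ADM{i:03d}", "M" if i % 2 == 0 else "F", ADMIXED))
    pop_counts = [(EAST_ASIAN, cfg.n_source1), (PAPUAN, cfg.n_source2)]
    pop_counts += [(p, cfg.n_outgroup) for p in outgroup_pops]
    for pop, count in pop_counts:
        for i in range(count):
            samples.append((f"{pop}_{i:03d}", "M" if i % 2 == 0 else "F", pop))
    sdf = pd.DataFrame(samples, columns=["id", "sex", "population"])

    calls = np.empty((n_var, len(sdf)), dtype=np.int8)
    p1 = freqs[EAST_ASIAN].to_numpy()
    p2 = freqs[PAPUAN].to_numpy()

    chrom_index = {c: np.flatnonzero(chrom_arr == c) for c in cfg.chromosomes}
    autosomes = [c for c in cfg.chromosomes if c != "X"]

    tract_rows = []
    papuan_dosage = np.full(len(sdf), np.nan)

    for j, row in enumerate(sdf.itertuples(index=False)):
        if row.population != ADMIXED:
            continue
        geno = np.zeros(n_var, dtype=np.int8)
        anc_sum = 0.0
        anc_n = 0
        for chrom in cfg.chromosomes:
            idx = chrom_index[chrom]
            on_x = chrom == "X"
            alpha = cfg.alpha_X if on_x else cfg.alpha_autosome
            n_hap = 1 if (on_x and row.sex == "M") else 2
            gp = gpos_arr[idx]
            dose = np.zeros(idx.size, dtype=np.int8)
            for hap in range(n_hap):
                anc, tracts = _hap_ancestry_at(
                    gp, cfg.chrom_length, alpha, cfg.admixture_generations, rng
                )
                p = np.where(anc, p2[idx], p1[idx])
                dose += (rng.random(idx.size) < p).astype(np.int8)
                if not on_x:
                    anc_sum += anc.sum()
                    anc_n += anc.size
                for s, e, a in tracts:
                    tract_rows.append(
                        (row.id, hap, chrom, s, e, PAPUAN if a else EAST_ASIAN)
                    )
            if n_hap == 1:
                dose *= 2  # haploid male X reported on the diploid dosage scale
            geno[idx] = dose
        calls[:, j] = geno
        papuan_dosage[j] = anc_sum / anc_n

    # unadmixed sources and outgroups: binomial draws from their own frequency
    for pop, _count in pop_counts:
        col = freqs[pop].to_numpy()
        jj = np.flatnonzero((sdf["population"] == pop).to_numpy())
        g = rng.binomial(2, col[:, None], size=(n_var, jj.size)).astype(np.int8)
        on_x = chrom_arr == "X"
        if on_x.any():
            male = (sdf["sex"].to_numpy()[jj] == "M")
            hap = rng.binomial(1, col[on_x][:, None], size=(int(on_x.sum()), int(male.sum())))
            g[np.ix_(on_x, np.flatnonzero(male))] = (2 * hap).astype(np.int8)
        calls[:, jj] = g

    if cfg.pseudo_haploid:
        het = calls == 1
        calls[het] = 2 * (rng.random(int(het.sum())) < 0.5).astype(np.int8)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    ds = GenotypeDataset(variants, sdf, calls, pseudo_haploid=cfg.pseudo_haploid)
    truth = {
        "alpha_autosome": cfg.alpha_autosome,
        "alpha_X": cfg.alpha_X,
        "admixture_generations": cfg.admixture_generations,
        "seed": cfg.seed,
        "tracts": pd.DataFrame(
            tract_rows,
            columns=["sample", "haplotype", "chrom", "start", "end", "ancestry"],
        ),
        "papuan_dosage": pd.Series(papuan_dosage, index=sdf["id"].to_numpy()),
        "source_freqs": freqs,
    }
    return ds, truth


def save_cohort(
    ds: GenotypeDataset, truth: dict, outdir: str | Path, packed: bool = False
) -> None:
    """Write EIGENSTRAT trio, tract TSV and truth JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_eigenstrat(ds, outdir / "cohort", packed=packed)
    truth["tracts"].to_csv(outdir / "tracts.tsv", sep="\t", index=False)
    scalars = {
        k: v for k, v in truth.items() if isinstance(v, (int, float, str, bool))
    }
    scalars["papuan_dosage"] = {
        k: (None if np.isnan(v) else float(v))
        for k, v in truth["papuan_dosage"].items()
    }
    (outdir / "truth.json").write_text(json.dumps(scalars, indent=2))


# ----------------------------------------------------------------------
# toy calibration curves
# ----------------------------------------------------------------------

def simulate_toy_calibration_curve(
    slope: float = 1.0,
    wiggle_amp: float = 0.0,
    reservoir_offset: float = 500.0,
    sigma: float = 15.0,
    wiggle_period: float = 1000.0,
):
    """Toy terrestrial/marine calibration-curve pair on [0, 6000] calBP.

    The terrestrial mean is ``slope * cal + wiggle_amp * sin(2 pi cal /
    wiggle_period)``; the marine curve is the terrestrial one shifted older
    by ``reservoir_offset`` 14C years.  Both carry a constant 1-sigma of
    ``sigma`` 14C years on a 5-year grid.  Stand-ins for the IntCal/Marine
    curve pair so the whole calibration chain is testable offline.
    """
    from .radiocarbon import CalibrationCurve

    if slope <= 0:
        raise ValueError("slope must be positive")
    cal = np.arange(0.0, 6000.0 + 5.0, 5.0)
    mu = slope * cal + wiggle_amp * np.sin(2 * np.pi * cal / wiggle_period)
    sig = np.full_like(cal, float(sigma))
    terrestrial = CalibrationCurve(cal, mu, sig, name="toy_terrestrial")
    marine = CalibrationCurve(cal, mu + reservoir_offset, sig.copy(), name="toy_marine")
    return terrestrial, marine


def write_curve_14c(curve, path: str | Path) -> None:
    """Write a curve in the three-column .14c convention (calBP, 14C, sigma)."""
    with open(path, "w") as fh:
        fh.write(f"# {getattr(curve, 'name', 'curve')}\n# calBP, 14C age BP, 1-sigma\n")
        for c, m, s in zip(curve.cal_grid, curve.mu, curve.sigma):
            fh.write(f"{c:.1f},{m:.2f},{s:.2f}\n")
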