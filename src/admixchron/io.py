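"""Genotype I/O and per-population allele statistics.

Data live in a :class:`GenotypeDataset`: a variant table, a sample table and
a dense matrix of alternate-allele dosages.  Pseudo-haploid data (the standard
representation for low-coverage ancient DNA, one randomly sampled allele per
site) use only dosages {0, 2, missing}; diploid reference panels use
{0, 1, 2, missing}.  Missing calls are 9 on disk (the EIGENSTRAT convention)
and -1 in memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: in-memory sentinel for a missing call (9 on disk)
MISSING = -1

AUTOSOMES = {str(c) for c in range(1, 23)}

_VARIANT_COLUMNS = ["id", "chrom", "gpos", "pos", "ref", "alt"]
_SAMPLE_COLUMNS = ["id", "sex", "population"]


class EigenstratError(ValueError):
    """Malformed or inconsistent EIGENSTRAT input."""


@dataclass
class GenotypeDataset:
    """Pseudo-haploid or diploid genotype matrix with variant and sample maps.

    Parameters
    ----------
    variants : pandas.DataFrame
        Columns ``id, chrom, gpos, pos, ref, alt``; ``gpos`` is the genetic
        position in Morgans, ``pos`` the 1-based physical position.
    samples : pandas.DataFrame
        Columns ``id, sex, population`` (sex in {M, F, U}); an optional
        ``date_bp`` column carries calibrated dates.
    calls : numpy.ndarray
        ``(n_variants, n_samples)`` int8 alternate-allele dosages with
        ``MISSING`` (-1) for no-calls.
    pseudo_haploid : bool, optional
        If None, auto-detected: a dataset with no dosage-1 call on the
        autosomes is flagged pseudo-haploid (with a warning).
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    pseudo_haploid: bool | None = None

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise EigenstratError(
                f"calls matrix {self.calls.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise EigenstratError(f"invalid dosage values: {np.unique(self.calls[bad])}")
        if self.pseudo_haploid is None:
            auto = self.variants["chrom"].isin(AUTOSOMES).to_numpy()
            has_het = (self.calls[auto] == 1).any()
            self.pseudo_haploid = not has_het
            warnings.warn(
                "pseudo_haploid flag not given; auto-detected as "
                f"{self.pseudo_haploid} (no dosage-1 autosomal call)"
                if self.pseudo_haploid
                else "pseudo_haploid flag not given; dataset contains "
                "heterozygous calls, treating as diploid",
                stacklevel=2,
            )
        self._check_invariants()

    # ------------------------------------------------------------------
    def _check_invariants(self) -> None:
        v = self.variants
        for chrom, grp in v.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            gpos = grp["gpos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise EigenstratError(f"physical positions not strictly increasing on chrom {chrom}")
            if not (np.diff(gpos) >= 0).all():
                raise EigenstratError(f"genetic positions decrease on chrom {chrom}")
        if self.pseudo_haploid:
            auto = v["chrom"].isin(AUTOSOMES).to_numpy()
            if (self.calls[auto] == 1).any():
                raise EigenstratError("pseudo-haploid dataset contains autosomal dosage 1")
        male = (self.samples["sex"] == "M").to_numpy()
        on_x = (v["chrom"] == "X").to_numpy()
        if male.any() and on_x.any():
            if (self.calls[np.ix_(on_x, male)] == 1).any():
                raise EigenstratError("male X calls must be haploid (no dosage 1)")

    # ------------------------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    # ------------------------------------------------------------------
    def restrict(
        self,
        variant_filter=None,
        sample_filter=None,
        chromosome_class: str | None = None,
    ) -> "GenotypeDataset":
        """Subset variants and/or samples, preserving order.

        ``variant_filter`` / ``sample_filter`` may be an iterable of ids or a
        boolean mask; ``chromosome_class`` is ``"autosomes"`` or ``"X"``.
        Raises on an empty result.
        """
        vmask = np.ones(self.n_variants, dtype=bool)
        smask = np.ones(self.n_samples, dtype=bool)
        if chromosome_class is not None:
            if chromosome_class == "autosomes":
                vmask &= self.variants["chrom"].isin(AUTOSOMES).to_numpy()
            elif chromosome_class == "X":
                vmask &= (self.variants["chrom"] == "X").to_numpy()
            else:
                raise ValueError(f"unknown chromosome_class {chromosome_class!r}")
        vmask &= _as_mask(variant_filter, self.variants["id"], "variant")
        smask &= _as_mask(sample_filter, self.samples["id"], "sample")
        if not vmask.any():
            raise ValueError("restriction removes every variant")
        if not smask.any():
            raise ValueError("restriction removes every sample")
        return GenotypeDataset(
            self.variants.loc[vmask],
            self.samples.loc[smask],
            self.calls[np.ix_(vmask, smask)],
            pseudo_haploid=self.pseudo_haploid,
        )

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.variants.copy(), self.samples.copy(), self.calls.copy(),
            pseudo_haploid=self.pseudo_haploid,
        )


def _as_mask(flt, ids: pd.Series, what: str) -> np.ndarray:
    if flt is None:
        return np.ones(len(ids), dtype=bool)
    flt = np.asarray(list(flt) if not isinstance(flt, np.ndarray) else flt)
    if flt.dtype == bool:
        if flt.size != len(ids):
            raise ValueError(f"{what} mask length {flt.size} != {len(ids)}")
        return flt
    wanted = set(flt)
    unknown = wanted - set(ids)
    if unknown:
        raise KeyError(f"unknown {what} ids: {sorted(unknown)[:5]}")
    return ids.isin(wanted).to_numpy()


# ----------------------------------------------------------------------
# allele frequencies
# ----------------------------------------------------------------------

def allele_frequencies(
    ds: GenotypeDataset, groups: dict[str, str] | None = None
) -> pd.DataFrame:
    """Per-population alternate-allele frequencies and allele counts.

    Allele-slot accounting: a diploid call contributes 2 slots and its dosage
    in alt alleles; a pseudo-haploid call and a male X call contribute 1 slot
    and dosage/2 alt alleles.  Returns a DataFrame indexed like ``ds.variants``
    with a two-level column index ``(population, {"freq", "n"})``; frequency is
    NaN exactly where the allele count is zero.
    """
    if groups is None:
        pop_of = dict(zip(ds.samples["id"], ds.samples["population"]))
    else:
        known = set(ds.samples["id"])
        missing = set(groups) - known
        if missing:
            raise KeyError(f"unknown samples in grouping: {sorted(missing)[:5]}")
        pop_of = dict(groups)

    sample_ids = ds.samples["id"].to_numpy()
    male = (ds.samples["sex"] == "M").to_numpy()
    on_x = (ds.variants["chrom"] == "X").to_numpy()

    calls = ds.calls
    called = calls != MISSING
    # slots per (variant, sample): 2 for diploid autosome/female-X, 1 otherwise
    haploid_sample = np.full(ds.n_samples, bool(ds.pseudo_haploid))
    slots = np.where(called, 2 - haploid_sample[None, :], 0).astype(np.int64)
    # male X is haploid regardless of ploidy convention
    if on_x.any() and male.any():
        mx = np.ix_(on_x, male)
        slots[mx] = np.where(called[mx], 1, 0)
    # alt-allele count: dosage, halved wherever only one slot is contributed
    alt = np.where(called, calls, 0).astype(np.float64)
    alt = np.where(slots == 1, alt / 2.0, alt)

    pops = sorted(set(pop_of.values()))
    out: dict[tuple[str, str], np.ndarray] = {}
    for pop in pops:
        members = np.array([pop_of.get(s) == pop for s in sample_ids])
        if not members.any():
            raise ValueError(f"population {pop!r} has no samples")
        n = slots[:, members].sum(axis=1)
        a = alt[:, members].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, a / np.maximum(n, 1), np.nan)
        out[(pop, "freq")] = p
        out[(pop, "n")] = n
    table = pd.DataFrame(out)
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["population", "stat"])
    return table


# ----------------------------------------------------------------------
# EIGENSTRAT read/write
# ----------------------------------------------------------------------

def read_eigenstrat(prefix: str | Path, pseudo_haploid: bool | None = None) -> GenotypeDataset:
    """Read an EIGENSTRAT trio ``prefix.{geno,snp,ind}`` (packed or ASCII)."""
    prefix = Path(prefix)
    snp_path, ind_path, geno_path = (
        prefix.with_suffix(prefix.suffix + ext) for ext in (".snp", ".ind", ".geno")
    )
    for p in (snp_path, ind_path, geno_path):
        if not p.exists():
            raise FileNotFoundError(p)

    variants = _read_snp(snp_path)
    samples = _read_ind(ind_path)
    with open(geno_path, "rb") as fh:
        head = fh.read(4)
    if head == b"GENO":
        calls = _read_packed_geno(geno_path, len(variants), len(samples))
    else:
        calls = _read_ascii_geno(geno_path, len(variants), len(samples))
    return GenotypeDataset(variants, samples, calls, pseudo_haploid=pseudo_haploid)


def write_eigenstrat(ds: GenotypeDataset, prefix: str | Path, packed: bool = False) -> None:
    """Write ``prefix.{geno,snp,ind}``; ``packed=True`` writes 2-bit .geno."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = ds.variants
    with open(str(prefix) + ".snp", "w") as fh:
        for row in v.itertuples(index=False):
            fh.write(
                f"{row.id}\t{row.chrom}\t{row.gpos:.10g}\t{int(row.pos)}\t{row.ref}\t{row.alt}\n"
            )
    with open(str(prefix) + ".ind", "w") as fh:
        for row in ds.samples.itertuples(index=False):
            fh.write(f"{row.id}\t{row.sex}\t{row.population}\n")
    disk = np.where(ds.calls == MISSING, 9, ds.calls).astype(np.uint8)
    if not packed:
        with open(str(prefix) + ".geno", "w") as fh:
            for rowvals in disk:
                fh.write("".join(map(str, rowvals)) + "\n")
    else:
        _write_packed_geno(disk, str(prefix) + ".geno")


def _read_snp(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise EigenstratError(f"{path}:{lineno}: expected >=4 columns")
            ref, alt = (parts[4], parts[5]) if len(parts) >= 6 else ("A", "C")
            chrom = {"23": "X"}.get(parts[1], parts[1])
            rows.append((parts[0], chrom, float(parts[2]), int(parts[3]), ref, alt))
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)


def _read_ind(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratError(f"{path}:{lineno}: expected 3 columns")
            if parts[1] not in {"M", "F", "U"}:
                raise EigenstratError(f"{path}:{lineno}: sex must be M/F/U")
            rows.append(tuple(parts))
    df = pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)
    if (df["population"] == "").any():
        raise EigenstratError(f"{path}: empty population label")
    return df


def _read_ascii_geno(path: Path, n_variants: int, n_samples: int) -> np.ndarray:
    calls = np.empty((n_variants, n_samples), dtype=np.int8)
    with open(path) as fh:
        lineno = 0
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if lineno >= n_variants:
                raise EigenstratError(
                    f"{path}: more genotype rows than the {n_variants} .snp lines"
                )
            if len(line) != n_samples:
                raise EigenstratError(
                    f"{path}:{lineno + 1}: row length {len(line)} != "
                    f"{n_samples} samples in .ind"
                )
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            bad = ~np.isin(row, [0, 1, 2, 9])
            if bad.any():
                raise EigenstratError(f"{path}:{lineno + 1}: unknown genotype code")
            calls[lineno] = np.where(row == 9, MISSING, row)
            lineno += 1
    if lineno != n_variants:
        raise EigenstratError(
            f"{path}: {lineno} genotype rows but {n_variants} .snp lines"
        )
    return calls


# packed EIGENSTRAT: 48-byte-min records of 2-bit genotypes, header in record 0
def _record_len(n_samples: int) -> int:
    return max(48, (n_samples + 3) // 4)


def _write_packed_geno(disk: np.ndarray, path: str) -> None:
    n_variants, n_samples = disk.shape
    rlen = _record_len(n_samples)
    header = f"GENO {n_samples} {n_variants} 0 0".encode().ljust(rlen, b"\x00")
    # 2-bit codes: 0->0, 1->1, 2->2, 9(missing)->3
    codes = np.where(disk == 9, 3, disk).astype(np.uint8)
    pad = (-n_samples) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0)
    codes = codes.reshape(n_variants, -1, 4)
    packed = (codes[:, :, 0] << 6) | (codes[:, :, 1] << 4) | (codes[:, :, 2] << 2) | codes[:, :, 3]
    with open(path, "wb") as fh:
        fh.write(header)
        for row in packed:
            fh.write(row.tobytes().ljust(rlen, b"\x00"))


def _read_packed_geno(path: Path, n_variants: int, n_samples: int) -> np.ndarray:
    rlen = _record_len(n_samples)
    raw = path.read_bytes()
    header = raw[:rlen].split(b"\x00")[0].split()
    if len(header) < 3 or header[0] != b"GENO":
        raise EigenstratError(f"{path}: malformed packed header")
    ns, nv = int(header[1]), int(header[2])
    if (ns, nv) != (n_samples, n_variants):
        raise EigenstratError(
            f"{path}: packed header says {nv} variants x {ns} samples, "
            f".snp/.ind say {n_variants} x {n_samples}"
        )
    body = np.frombuffer(raw[rlen:], dtype=np.uint8)
    if body.size != n_variants * rlen:
        raise EigenstratError(f"{path}: truncated packed genotype body")
    body = body.reshape(n_variants, rlen)[:, : (n_samples + 3) // 4]
    codes = np.empty((n_variants, 4 * body.shape[1]), dtype=np.uint8)
    codes[:, 0::4] = body >> 6
    codes[:, 1::4] = (body >> 4) & 3
    codes[:, 2::4] = (body >> 2) & 3
    codes[:, 3::4] = body & 3
    codes = codes[:, :n_samples]
    return np.where(codes == 3, MISSING, codes).astype(np.int8)


# ----------------------------------------------------------------------
# unit helpers and auxiliary formats
# ----------------------------------------------------------------------

def morgans_to_cm(x):
    return np.asarray(x, dtype=float) * 100.0


def cm_to_morgans(x):
    return np.asarray(x, dtype=float) / 100.0


def read_population_table(path: str | Path) -> dict[str, str]:
    """TSV of (sample_id, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "population"], dtype=str)
    return dict(zip(df["id"], df["population"]))


def read_vcf_biallelic(path: str | Path) -> GenotypeDataset:
    """Minimal VCF import: biallelic SNPs only, GT field, no genetic map.

    Genetic positions are filled with a 1 cM/Mb surrogate; supply a real map
    for dating work.
    """
    variants = []
    sample_ids: list[str] = []
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.rstrip("\n").split("\t")[9:]
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                continue
            chrom = chrom.removeprefix("chr")
            dosages = []
            for entry in parts[9:]:
                gt = entry.split(":")[0].replace("|", "/")
                alleles = [a for a in gt.split("/") if a != "."]
                dosages.append(sum(int(a) for a in alleles) if alleles else MISSING)
            variants.append((vid if vid != "." else f"{chrom}_{pos}", chrom, pos * 1e-8, pos, ref, alt))
            rows.append(dosages)
    vdf = pd.DataFrame(variants, columns=_VARIANT_COLUMNS)
    sdf = pd.DataFrame({"id": sample_ids, "sex": "U", "population": "VCF"})
    return GenotypeDataset(vdf, sdf, np.array(rows, dtype=np.int8), pseudo_haploid=False)
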