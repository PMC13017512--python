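"""Genotype panel data model and I/O.

The substrate of every analysis in this package is a :class:`GenotypePanel`:
a biallelic site table, per-sample metadata (including ploidy — 1 for
pseudo-haploid ancient samples, 2 for diploid moderns) and a sites × samples
matrix of alt-allele dosages with ``MISSING = -1``.

Conventions
-----------
* Positions are 1-based, matching EIGENSTRAT and VCF.
* Dosage counts the alt allele. Polarity is irrelevant to f-statistics but is
  fixed for determinism.
* Pseudo-haploid calls are produced by drawing a single read uniformly among
  reads carrying the ref or alt allele at each site; reads carrying other
  bases are excluded from the pool, matching biallelic-site semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DimensionError,
    FormatError,
    InvariantError,
    PopulationLookupError,
)

logger = logging.getLogger(__name__)

MISSING = -1

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SAMPLE_COLUMNS = [
    "sample_id",
    "population",
    "species",
    "ploidy",
    "latitude",
    "longitude",
    "age_bp",
    "coverage",
]


def transversion_flags(ref: Sequence[str], alt: Sequence[str]) -> np.ndarray:
    """True where {ref, alt} is not the transition pair {A,G} or {C,T}."""
    ref = np.asarray(ref, dtype=object)
    alt = np.asarray(alt, dtype=object)
    key = np.where(ref < alt, ref + alt, alt + ref)
    return ~np.isin(key.astype(str), ("AG", "CT"))


def make_sites(
    chrom: Sequence,
    pos: Sequence[int],
    ref: Sequence[str],
    alt: Sequence[str],
    site_id: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build and validate a site table.

    Raises :class:`FormatError` for non-ACGT or identical alleles and
    :class:`InvariantError` if positions are not strictly increasing within a
    chromosome.
    """
    chrom = np.asarray(chrom, dtype=str)
    pos = np.asarray(pos, dtype=np.int64)
    ref = np.asarray(ref, dtype=str)
    alt = np.asarray(alt, dtype=str)
    n = len(pos)
    if not (len(chrom) == len(ref) == len(alt) == n):
        raise DimensionError("site columns have unequal lengths")
    if n and (not np.isin(ref, BASES).all() or not np.isin(alt, BASES).all()):
        raise FormatError("alleles must be one of A, C, G, T")
    if n and (ref == alt).any():
        raise FormatError("ref and alt alleles must differ")
    if site_id is None:
        site_id = np.array([f"{c}_{p}" for c, p in zip(chrom, pos)])
    sites = pd.DataFrame(
        {
            "site_id": np.asarray(site_id, dtype=str),
            "chrom": chrom,
            "pos": pos,
            "ref_allele": ref,
            "alt_allele": alt,
            "is_transversion": transversion_flags(ref, alt) if n else np.array([], bool),
        }
    )
    for _, grp in sites.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
            raise InvariantError("positions must be strictly increasing within a chromosome")
    return sites


def make_samples(
    sample_id: Sequence[str],
    population: Sequence[str],
    *,
    species: Sequence[str] | str = "dog",
    ploidy: Sequence[int] | int = 1,
    latitude: Sequence[float] | float = np.nan,
    longitude: Sequence[float] | float = np.nan,
    age_bp: Sequence[float] | float = 0.0,
    coverage: Sequence[float] | float = np.nan,
) -> pd.DataFrame:
    """Build and validate a sample-metadata table."""
    n = len(sample_id)

    def _col(v, dtype):
        arr = np.asarray(v, dtype=dtype)
        return np.full(n, arr, dtype=dtype) if arr.ndim == 0 else arr

    df = pd.DataFrame(
        {
            "sample_id": np.asarray(sample_id, dtype=str),
            "population": _col(population, object),
            "species": _col(species, object),
            "ploidy": _col(ploidy, np.int64),
            "latitude": _col(latitude, np.float64),
            "longitude": _col(longitude, np.float64),
            "age_bp": _col(age_bp, np.float64),
            "coverage": _col(coverage, np.float64),
        }
    )
    _validate_samples(df)
    return df


def _validate_samples(df: pd.DataFrame) -> None:
    if not df["ploidy"].isin([1, 2]).all():
        raise InvariantError("ploidy must be 1 or 2")
    lat = df["latitude"].to_numpy()
    lon = df["longitude"].to_numpy()
    ok_lat = np.isnan(lat) | ((lat >= -90) & (lat <= 90))
    ok_lon = np.isnan(lon) | ((lon >= -180) & (lon <= 180))
    if not (ok_lat.all() and ok_lon.all()):
        raise InvariantError("latitude/longitude out of range")
    if df["sample_id"].duplicated().any():
        raise InvariantError("duplicate sample_id")


@dataclass
class GenotypePanel:
    """Sites × samples alt-allele dosage matrix with metadata.

    ``calls`` holds integers in {0, ..., ploidy} or ``MISSING`` (-1).
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.samples)):
            raise DimensionError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        _validate_samples(self.samples)
        ploidy = self.samples["ploidy"].to_numpy()
        if self.calls.size:
            if self.calls.min() < MISSING:
                raise InvariantError("calls below MISSING sentinel")
            over = (self.calls > ploidy[np.newaxis, :]).any()
            if over:
                raise InvariantError("dosage exceeds sample ploidy")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.samples["population"]))

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.samples["population"] == population).to_numpy())
        if idx.size == 0:
            raise PopulationLookupError(population)
        return idx

    def take_sites(self, selector) -> "GenotypePanel":
        sel = np.asarray(selector)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return GenotypePanel(
            self.sites.iloc[sel].reset_index(drop=True),
            self.samples,
            self.calls[sel, :],
        )

    def take_samples(self, selector) -> "GenotypePanel":
        sel = np.asarray(selector)
        if sel.dtype == bool:
            sel = np.flatnonzero(sel)
        return GenotypePanel(
            self.sites,
            self.samples.iloc[sel].reset_index(drop=True),
            self.calls[:, sel],
        )

    def population_frequencies(
        self, populations: Sequence[str]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele frequency per site for each population.

        Returns ``(freq, n_chrom)``: both (n_sites, n_populations); ``freq``
        is NaN where every sample of the population is missing.
        """
        freq = np.empty((self.n_sites, len(populations)))
        nchrom = np.zeros((self.n_sites, len(populations)), dtype=np.int64)
        ploidy = self.samples["ploidy"].to_numpy()
        for j, pop in enumerate(populations):
            idx = self.population_indices(pop)
            sub = self.calls[:, idx]
            valid = sub != MISSING
            denom = (valid * ploidy[idx][np.newaxis, :]).sum(axis=1)
            num = np.where(valid, sub, 0).sum(axis=1)
            with np.errstate(invalid="ignore"):
                freq[:, j] = np.where(denom > 0, num / np.maximum(denom, 1), np.nan)
            nchrom[:, j] = denom
        return freq, nchrom


def allele_frequency(
    panel: GenotypePanel, population: str, site_index: int
) -> tuple[float | None, int]:
    """Alt-allele frequency and chromosome count at one site.

    Returns ``(None, 0)`` when every sample of the population is missing.
    """
    freq, nchrom = panel.population_frequencies([population])
    f = freq[site_index, 0]
    n = int(nchrom[site_index, 0])
    return (None, 0) if np.isnan(f) else (float(f), n)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def read_eigenstrat(
    geno_path,
    snp_path,
    ind_path,
    *,
    ploidies: Sequence[int] | None = None,
    metadata: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Read an EIGENSTRAT geno/snp/ind triplet.

    '9' maps to MISSING. Ploidy is taken from ``ploidies`` or ``metadata``
    when given; otherwise a sample is inferred diploid iff it carries any
    dosage-2 call (pseudo-haploid panels carry only 0/1/9).
    """
    ind = pd.read_csv(ind_path, sep=r"\s+", header=None, names=["sample_id", "sex", "population"], dtype=str)
    snp = pd.read_csv(
        snp_path,
        sep=r"\s+",
        header=None,
        names=["site_id", "chrom", "gpos", "pos", "ref_allele", "alt_allele"],
        dtype={"site_id": str, "chrom": str, "ref_allele": str, "alt_allele": str},
    )
    n_samples = len(ind)
    rows: list[np.ndarray] = []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if len(line) != n_samples:
                raise FormatError(
                    f"geno line {lineno} has width {len(line)}, expected {n_samples}"
                )
            row = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            if not np.isin(row, (0, 1, 2, 9)).all():
                raise FormatError(f"geno line {lineno} contains non-genotype characters")
            rows.append(row.astype(np.int8))
    calls = np.vstack(rows) if rows else np.empty((0, n_samples), dtype=np.int8)
    calls[calls == 9] = MISSING
    if len(snp) != calls.shape[0]:
        raise FormatError(
            f"snp file has {len(snp)} rows but geno has {calls.shape[0]}"
        )
    sites = make_sites(
        snp["chrom"], snp["pos"], snp["ref_allele"], snp["alt_allele"], snp["site_id"]
    )
    if ploidies is not None:
        ploidy = np.asarray(ploidies, dtype=np.int64)
    elif metadata is not None:
        meta = metadata.set_index("sample_id")
        ploidy = meta.loc[ind["sample_id"], "ploidy"].to_numpy(dtype=np.int64)
    else:
        ploidy = np.where((calls == 2).any(axis=0), 2, 1)
    if metadata is not None:
        meta = metadata.set_index("sample_id").loc[ind["sample_id"]].reset_index()
        samples = make_samples(
            meta["sample_id"],
            meta["population"],
            species=meta.get("species", "dog"),
            ploidy=ploidy,
            latitude=meta.get("latitude", np.nan),
            longitude=meta.get("longitude", np.nan),
            age_bp=meta.get("age_bp", 0.0),
            coverage=meta.get("coverage", np.nan),
        )
    else:
        samples = make_samples(ind["sample_id"], ind["population"], ploidy=ploidy)
    return GenotypePanel(sites, samples, calls)


def write_eigenstrat(panel: GenotypePanel, out_prefix) -> tuple[Path, Path, Path]:
    """Write geno/snp/ind files; MISSING becomes '9'.

    Column order in geno equals the panel's sample order.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")

    digits = panel.calls.astype(np.int16).copy()
    digits[digits == MISSING] = 9
    with open(geno_path, "w") as fh:
        for row in digits:
            fh.write("".join(map(str, row)) + "\n")
    with open(snp_path, "w") as fh:
        for rec in panel.sites.itertuples(index=False):
            fh.write(
                f"{rec.site_id}\t{rec.chrom}\t0.0\t{rec.pos}\t{rec.ref_allele}\t{rec.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for rec in panel.samples.itertuples(index=False):
            fh.write(f"{rec.sample_id}\tU\t{rec.population}\n")
    return geno_path, snp_path, ind_path


def read_metadata(path) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, population, species, ploidy, ...)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = set(("sample_id", "population", "ploidy")) - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    return df


def write_metadata(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    samples.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# VCF subset reader
# ---------------------------------------------------------------------------

def read_vcf_subset(
    vcf_path, site_filter: Callable[[object], bool] | None = None
) -> GenotypePanel:
    """Read biallelic SNVs with GT from a VCF into a diploid panel.

    Non-SNV and multiallelic records, records failing ``site_filter``, and
    records at non-increasing positions are dropped with a logged count;
    half-calls become MISSING.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if not vcf.samples:
        raise FormatError("VCF has no genotype columns (missing GT data)")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    skipped = dropped_halfcalls = 0
    last: dict[str, int] = {}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped += 1
            continue
        if var.REF not in BASES or var.ALT[0] not in BASES:
            skipped += 1
            continue
        if site_filter is not None and not site_filter(var):
            skipped += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            skipped += 1
            continue
        last[var.CHROM] = var.POS
        row = np.full(len(vcf.samples), MISSING, dtype=np.int8)
        for k, g in enumerate(var.genotypes):
            alleles = g[:-1]
            if any(a < 0 for a in alleles):
                dropped_halfcalls += 1
                continue
            row[k] = sum(alleles)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(row)
    logger.info(
        "read_vcf_subset: kept %d records, skipped %d, half-calls set missing %d",
        len(rows), skipped, dropped_halfcalls,
    )
    calls = np.vstack(rows) if rows else np.empty((0, len(vcf.samples)), dtype=np.int8)
    sites = make_sites(chroms, poss, refs, alts)
    samples = make_samples(list(vcf.samples), list(vcf.samples), ploidy=2, species="dog")
    return GenotypePanel(sites, samples, calls)


# ---------------------------------------------------------------------------
# Pseudo-haploidization from base counts
# ---------------------------------------------------------------------------

@dataclass
class BaseCounts:
    """Per-(site, sample) read counts supporting each of A, C, G, T."""

    sample_ids: list[str]
    counts: np.ndarray  # (n_sites, n_samples, 4), A/C/G/T order

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 4:
            raise DimensionError("counts must have shape (n_sites, n_samples, 4)")
        if self.counts.shape[1] != len(self.sample_ids):
            raise DimensionError("counts second axis must match sample_ids")
        if self.counts.size and (self.counts < 0).any():
            raise InvariantError("read counts must be non-negative")


def pseudohaploidize(
    counts: BaseCounts,
    sites: pd.DataFrame,
    seed: int,
    samples: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Draw one read uniformly among ref/alt reads at each site.

    Sites with zero eligible reads become MISSING; the result is a
    ploidy-1 panel with calls in {0, 1, MISSING}.
    """
    if counts.counts.shape[0] != len(sites):
        raise DimensionError("counts and site table have different site counts")
    rng = np.random.default_rng(seed)
    ridx = np.array([_BASE_INDEX[b] for b in sites["ref_allele"]])
    aidx = np.array([_BASE_INDEX[b] for b in sites["alt_allele"]])
    site_ix = np.arange(len(sites))[:, None]
    samp_ix = np.arange(len(counts.sample_ids))[None, :]
    refc = counts.counts[site_ix, samp_ix, ridx[:, None]]
    altc = counts.counts[site_ix, samp_ix, aidx[:, None]]
    tot = refc + altc
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(tot > 0, altc / np.maximum(tot, 1), 0.0)
    draw = (rng.random(tot.shape) < p_alt).astype(np.int8)
    calls = np.where(tot > 0, draw, np.int8(MISSING)).astype(np.int8)
    if samples is None:
        samples = make_samples(counts.sample_ids, counts.sample_ids, ploidy=1)
    return GenotypePanel(sites.reset_index(drop=True), samples, calls)


def filter_transversions(panel: GenotypePanel) -> GenotypePanel:
    """Retain only transversion sites (order preserved); idempotent."""
    return panel.take_sites(panel.sites["is_transversion"].to_numpy())
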