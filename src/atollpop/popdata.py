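"""Domain types, genotype/survey file I/O, RAD read QC, and locus filtering.

Genotypes are diploid biallelic SNP calls coded as the number of copies of
the designated alternate allele (0, 1, 2) with ``MISSING`` (-1) for no-calls.
All downstream statistics (heterozygosity, pi, kinship, composite LD) are
symmetric under swapping which allele is "alternate", so the coding choice
is a convention, not a modelling decision.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING: int = -1

VALID_STRATA = ("shallow", "deep")


class ParseError(ValueError):
    """A file did not parse in the expected dialect."""


class EmptyInputError(ValueError):
    """An input contained no usable records."""


class AbsentDataError(LookupError):
    """A query matched no data (e.g. no transects for a species/year)."""


class DomainError(ValueError):
    """A quantity is outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LocusMeta:
    """Metadata for one biallelic SNP column."""

    id: str
    chrom: str | None = None
    pos: int | None = None  # 1-based, VCF convention
    ref: str | None = None
    alt: str | None = None


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for ``n`` individuals at ``L`` SNPs.

    Parameters
    ----------
    individuals
        Unique sample identifiers, one per row of ``calls``.
    loci
        Per-column metadata; ``len(loci)`` must equal ``calls.shape[1]``.
    calls
        ``(n, L)`` integer array over ``{0, 1, 2, MISSING}`` counting copies
        of the alternate allele.
    locus_length_bp
        Number of sequenced sites per RAD locus (the tag length). Used to
        convert per-SNP diversity into per-site nucleotide diversity.
    """

    individuals: list[str]
    loci: list[LocusMeta]
    calls: np.ndarray
    locus_length_bp: int = 80
    ploidy: int = field(default=2, init=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D individuals x loci array")
        n, L = self.calls.shape
        if n < 1:
            raise EmptyInputError("a genotype matrix needs at least one individual")
        if len(self.individuals) != n:
            raise ValueError("individuals list does not match call matrix rows")
        if len(self.loci) != L:
            raise ValueError("locus list does not match call matrix columns")
        if len(set(self.individuals)) != n:
            raise ValueError("sample identifiers must be unique")
        ids = [m.id for m in self.loci]
        if len(set(ids)) != L:
            raise ValueError("locus identifiers must be unique")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def subset_individuals(self, keep: Sequence[int] | Sequence[str]) -> "GenotypeMatrix":
        """Return a copy restricted to the given individuals (index or id)."""
        if len(keep) and isinstance(keep[0], str):
            index = {s: i for i, s in enumerate(self.individuals)}
            rows = [index[s] for s in keep]
        else:
            rows = list(keep)  # type: ignore[arg-type]
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in rows],
            loci=list(self.loci),
            calls=self.calls[rows, :].copy(),
            locus_length_bp=self.locus_length_bp,
        )

    def subset_loci(self, keep: Sequence[int]) -> "GenotypeMatrix":
        """Return a copy restricted to the given locus columns."""
        rows = np.asarray(list(keep), dtype=int)
        return GenotypeMatrix(
            individuals=list(self.individuals),
            loci=[self.loci[j] for j in rows],
            calls=self.calls[:, rows].copy(),
            locus_length_bp=self.locus_length_bp,
        )


@dataclass
class HabitatModel:
    """Planar reef habitat split into a shallow (0-50 m) and deep (50-100 m)
    stratum, with a per-species discount on deep density.

    ``deep_density_factor`` is the fraction of the shallow density assumed to
    hold in the deep stratum (1.0 = undiminished; 0.2 = one fifth).
    """

    shallow_area_km2: float
    deep_area_km2: float
    deep_density_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.shallow_area_km2 < 0 or self.deep_area_km2 < 0:
            raise ValueError("habitat areas must be non-negative")
        if not (0.0 < self.deep_density_factor <= 1.0):
            raise ValueError("deep_density_factor must be in (0, 1]")

    @property
    def shallow_area_ha(self) -> float:
        return self.shallow_area_km2 * 100.0

    @property
    def deep_area_ha(self) -> float:
        return self.deep_area_km2 * 100.0

    def effective_area_ha(self, depth_range: str = "to_100m") -> float:
        """Habitat area weighted by the deep-density discount, in hectares."""
        if depth_range == "shallow_only":
            return self.shallow_area_ha
        if depth_range == "to_100m":
            return self.shallow_area_ha + self.deep_density_factor * self.deep_area_ha
        raise ValueError(f"unknown depth range {depth_range!r}")


@dataclass
class ReadQCParams:
    """Parameters of the RAD read trim/quality/demultiplex rule.

    Reads are truncated at the 3' end to ``trim_to_bp`` bases, kept only if
    the product of per-base correctness probabilities 1 - 10**(-Q/10) over
    those bases is at least ``min_quality_product``, then stripped of the
    5' barcode and restriction-site residue.
    """

    trim_to_bp: int = 92
    barcode_bp: int = 6
    residue_bp: int = 6
    min_quality_product: float = 0.80

    def __post_init__(self) -> None:
        if self.trim_to_bp <= self.barcode_bp + self.residue_bp:
            raise ValueError("trim length must exceed barcode + residue length")
        if not (0.0 < self.min_quality_product <= 1.0):
            raise ValueError("min_quality_product must be in (0, 1]")

    @property
    def final_locus_bp(self) -> int:
        return self.trim_to_bp - self.barcode_bp - self.residue_bp


@dataclass
class SurveyTable:
    """Validated per-transect fish counts.

    Columns: site (str), year (int), stratum ({shallow, deep}),
    transect_area_m2 (float > 0), species (str), count (int >= 0).
    """

    df: pd.DataFrame

    REQUIRED = ("site", "year", "stratum", "transect_area_m2", "species", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ParseError(f"survey table missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        for i, row in self.df.iterrows():
            if row["stratum"] not in VALID_STRATA:
                raise ParseError(
                    f"row {i + 1}: unknown stratum {row['stratum']!r} "
                    f"(expected one of {VALID_STRATA})"
                )
            if row["count"] < 0:
                raise ParseError(f"row {i + 1}: negative count {row['count']}")
            if row["transect_area_m2"] <= 0:
                raise ParseError(
                    f"row {i + 1}: non-positive transect area {row['transect_area_m2']}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())


# ---------------------------------------------------------------------------
# Genotype file I/O
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a biallelic diploid SNP matrix from VCF, Genepop, or CSV.

    Multi-allelic records are skipped (with a logged count); missing
    genotypes map to :data:`MISSING`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "csv":
        return _read_genotype_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str) -> None:
    """Write a genotype matrix in VCF, Genepop, or CSV (round-trip safe)."""
    path = Path(path)
    if format == "vcf":
        _write_vcf(g, path)
    elif format == "genepop":
        _write_genepop(g, path)
    elif format == "csv":
        _write_genotype_csv(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise ParseError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vcf.samples)
    if not samples:
        raise EmptyInputError(f"{path}: VCF contains no samples")
    loci: list[LocusMeta] = []
    columns: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[i] = a + b
        columns.append(col)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        loci.append(
            LocusMeta(id=vid, chrom=var.CHROM, pos=var.POS, ref=var.REF, alt=var.ALT[0])
        )
    if n_multi:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, n_multi)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals=samples, loci=loci, calls=calls)


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({m.chrom or "un" for m in g.loci})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        for j, m in enumerate(g.loci):
            chrom = m.chrom or "un"
            pos = m.pos if m.pos is not None else j + 1
            ref = m.ref or "A"
            alt = m.alt or "C"
            gts = "\t".join(code_to_gt[int(c)] for c in g.calls[:, j])
            fh.write(f"{chrom}\t{pos}\t{m.id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _read_genepop(path: Path) -> GenotypeMatrix:
    """Genepop dialect: title line, one locus name per line (or one
    comma-separated line), POP separators, then ``id , a1a2 a1a2 ...`` rows
    with 2- or 3-digit allele codes. Populations are concatenated.

    The alternate allele is the minor allele over the whole file (ties broken
    toward the numerically larger allele code); loci with more than two
    alleles are skipped with a logged count.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: too short to be a Genepop file")
    # locus names: lines 2.. until first POP
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: no POP line found")
    names: list[str] = []
    rows: list[list[str]] = []
    for ln_no in range(i, len(lines)):
        line = lines[ln_no]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            continue
        if "," not in line:
            raise ParseError(f"{path}: line {ln_no + 1}: expected 'id , genotypes'")
        ind_id, geno_part = line.split(",", 1)
        alleles = geno_part.split()
        if len(alleles) != len(locus_names):
            raise ParseError(
                f"{path}: line {ln_no + 1}: {len(alleles)} genotypes for "
                f"{len(locus_names)} loci"
            )
        names.append(ind_id.strip())
        rows.append(alleles)
    if not names:
        raise EmptyInputError(f"{path}: no individuals found")

    n, L = len(names), len(locus_names)
    # decode two alleles per genotype string (2- or 3-digit dialect)
    a1 = np.zeros((n, L), dtype=int)
    a2 = np.zeros((n, L), dtype=int)
    for r, alleles in enumerate(rows):
        for c, tok in enumerate(alleles):
            if len(tok) == 4:
                w = 2
            elif len(tok) == 6:
                w = 3
            else:
                raise ParseError(
                    f"{path}: individual {names[r]!r}, locus {locus_names[c]!r}: "
                    f"bad genotype token {tok!r}"
                )
            a1[r, c] = int(tok[:w])
            a2[r, c] = int(tok[w:])

    keep: list[int] = []
    loci: list[LocusMeta] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for c in range(L):
        pair = np.stack([a1[:, c], a2[:, c]])
        observed = np.unique(pair[pair > 0])
        if len(observed) > 2:
            n_multi += 1
            continue
        if len(observed) == 0:
            alleles2 = (1, 2)  # fully missing column: arbitrary ref/alt
        elif len(observed) == 1:
            alleles2 = (int(observed[0]), int(observed[0]))
        else:
            counts = {int(x): int((pair == x).sum()) for x in observed}
            # minor allele = alternate; ties -> larger code, deterministically
            alt = min(counts, key=lambda x: (counts[x], -x))
            ref = next(x for x in counts if x != alt)
            alleles2 = (ref, alt)
        ref_code, alt_code = alleles2
        missing = (a1[:, c] == 0) | (a2[:, c] == 0)
        col = ((a1[:, c] == alt_code).astype(np.int8) + (a2[:, c] == alt_code)).astype(
            np.int8
        )
        if ref_code == alt_code:  # monomorphic: all ref
            col[:] = 0
        col[missing] = MISSING
        keep.append(c)
        cols.append(col)
        loci.append(
            LocusMeta(id=locus_names[c], ref=f"{ref_code:02d}", alt=f"{alt_code:02d}")
        )
    if n_multi:
        logger.info("%s: skipped %d multi-allelic Genepop loci", path, n_multi)
    calls = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int8)
    return GenotypeMatrix(individuals=names, loci=loci, calls=calls)


def _write_genepop(g: GenotypeMatrix, path: Path) -> None:
    """Two-digit dialect; ref allele written as 01, alt as 02, missing 0000.

    Writing makes allele 02 the alternate regardless of frequency, so a
    read-back designates the same alternate only when it is minor; the calls
    round-trip exactly up to the allele-symmetric recoding (which no
    downstream statistic distinguishes) and exactly when alt is minor.
    """
    with open(path, "w") as fh:
        fh.write("atollpop genotype export\n")
        for m in g.loci:
            fh.write(f"{m.id}\n")
        fh.write("POP\n")
        code_to_tok = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
        for i, ind in enumerate(g.individuals):
            toks = " ".join(code_to_tok[int(c)] for c in g.calls[i, :])
            fh.write(f"{ind} , {toks}\n")


def _read_genotype_csv(path: Path) -> GenotypeMatrix:
    """CSV dialect: header ``individual,<locus1>,<locus2>,...``; calls are
    0/1/2 or empty/NA for missing."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if not header or header[0] != "individual":
            raise ParseError(f"{path}: line 1: expected header starting 'individual'")
        locus_names = header[1:]
        names: list[str] = []
        rows: list[list[int]] = []
        for ln_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(f"{path}: line {ln_no}: wrong field count")
            names.append(row[0])
            vals: list[int] = []
            for tok in row[1:]:
                tok = tok.strip()
                if tok in ("", "NA", "."):
                    vals.append(MISSING)
                elif tok in ("0", "1", "2"):
                    vals.append(int(tok))
                else:
                    raise ParseError(f"{path}: line {ln_no}: bad call {tok!r}")
            rows.append(vals)
    if not names:
        raise EmptyInputError(f"{path}: no individuals found")
    calls = np.array(rows, dtype=np.int8)
    loci = [LocusMeta(id=name) for name in locus_names]
    return GenotypeMatrix(individuals=names, loci=loci, calls=calls)


def _write_genotype_csv(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual"] + [m.id for m in g.loci])
        for i, ind in enumerate(g.individuals):
            writer.writerow(
                [ind] + ["" if c == MISSING else str(int(c)) for c in g.calls[i, :]]
            )


# ---------------------------------------------------------------------------
# Locus filtering
# ---------------------------------------------------------------------------


def locus_allele_stats(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (alt frequency, non-missing count, completeness fraction).

    Frequencies use non-missing calls only (pairwise-available convention);
    a fully missing locus gets frequency NaN.
    """
    present = g.calls != MISSING
    n_nonmiss = present.sum(axis=0)
    alt_copies = np.where(present, g.calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_nonmiss > 0, alt_copies / (2.0 * n_nonmiss), np.nan)
    completeness = n_nonmiss / g.n_individuals
    return freq, n_nonmiss, completeness


def filter_loci(
    g: GenotypeMatrix, maf_min: float = 0.05, completeness_min: float = 0.8
) -> GenotypeMatrix:
    """Keep loci with minor-allele frequency >= ``maf_min`` (over non-missing
    calls) and non-missing fraction >= ``completeness_min``.

    Removing every locus is legal (empty matrix with a warning), since a
    stringent filter on low-diversity data can do exactly that.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0.0 <= completeness_min <= 1.0):
        raise ValueError("completeness_min must be in [0, 1]")
    freq, _, completeness = locus_allele_stats(g)
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freq, 1.0 - freq)
    keep = np.flatnonzero(
        (completeness >= completeness_min) & ~np.isnan(maf) & (maf >= maf_min)
    )
    if keep.size == 0:
        logger.warning("filter_loci removed every locus (of %d)", g.n_loci)
    return g.subset_loci(keep)


# ---------------------------------------------------------------------------
# RAD read QC / demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Bookkeeping for one demultiplex/QC pass. kept + dropped + unassigned
    equals the number of input reads."""

    n_input: int = 0
    n_kept: int = 0
    n_dropped_short: int = 0
    n_dropped_quality: int = 0
    n_unassigned: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_short + self.n_dropped_quality

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "n_kept": self.n_kept,
                "n_dropped": self.n_dropped,
                "n_dropped_short": self.n_dropped_short,
                "n_dropped_quality": self.n_dropped_quality,
                "n_unassigned": self.n_unassigned,
                "per_sample": self.per_sample,
            },
            indent=2,
            sort_keys=True,
        )


def quality_product(quals: Sequence[int]) -> float:
    """Product of per-base correctness probabilities 1 - 10**(-Q/10).

    Computed in log space so 92-base products do not underflow gradually.
    """
    q = np.asarray(quals, dtype=float)
    p_err = np.power(10.0, -q / 10.0)
    if np.any(p_err >= 1.0):
        return 0.0
    return float(np.exp(np.log1p(-p_err).sum()))


def demux_and_qc_reads(
    fastq: str | Path | Iterable,
    barcodes: Mapping[str, str],
    params: ReadQCParams | None = None,
) -> tuple[dict[str, list], QCReport]:
    """Trim, quality-filter, and demultiplex RAD reads.

    Each kept read is truncated to ``params.trim_to_bp`` bases (3' trim),
    must satisfy the quality-product rule over those bases, is assigned by
    exact match of its first ``barcode_bp`` bases, and is emitted as the
    remaining tag after removing barcode + restriction-site residue from the
    5' end.

    Parameters
    ----------
    fastq
        Path to a FASTQ file (Phred+33) or an iterable of Bio.SeqRecord.
    barcodes
        Map of barcode sequence -> sample name; barcodes must be unique
        ``barcode_bp``-mers and samples distinct per barcode.

    Returns
    -------
    (per-sample lists of trimmed SeqRecord, QCReport)
    """
    from Bio import SeqIO

    params = params or ReadQCParams()
    bw = params.barcode_bp
    for bc in barcodes:
        if len(bc) != bw:
            raise ValueError(f"barcode {bc!r} is not {bw} bp")
    if len(set(barcodes.values())) != len(barcodes):
        raise ValueError("two barcodes map to the same sample")

    if isinstance(fastq, (str, Path)):
        reads: Iterator = SeqIO.parse(str(fastq), "fastq")
    else:
        reads = iter(fastq)

    out: dict[str, list] = {s: [] for s in barcodes.values()}
    report = QCReport(per_sample={s: 0 for s in barcodes.values()})
    strip = params.barcode_bp + params.residue_bp
    for rec in reads:
        report.n_input += 1
        if len(rec) < params.trim_to_bp:
            report.n_dropped_short += 1
            continue
        trimmed = rec[: params.trim_to_bp]
        quals = trimmed.letter_annotations["phred_quality"]
        if quality_product(quals) < params.min_quality_product:
            report.n_dropped_quality += 1
            continue
        bc = str(trimmed.seq[:bw])
        sample = barcodes.get(bc)
        if sample is None:
            report.n_unassigned += 1
            continue
        tag = trimmed[strip:]
        tag.id = rec.id
        tag.description = sample
        out[sample].append(tag)
        report.n_kept += 1
        report.per_sample[sample] += 1
    return out, report


# ---------------------------------------------------------------------------
# Survey I/O
# ---------------------------------------------------------------------------


def read_survey_csv(path: str | Path) -> SurveyTable:
    """Read and validate a per-transect survey CSV.

    Expected header: site,year,stratum,transect_area_m2,species,count.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file") from None
    missing = [c for c in SurveyTable.REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df):
        try:
            df["year"] = df["year"].astype(int)
            df["count"] = df["count"].astype(int)
            df["transect_area_m2"] = df["transect_area_m2"].astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: non-numeric year/count/area ({exc})") from exc
    return SurveyTable(df=df)


def write_survey_csv(table: SurveyTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, columns=list(SurveyTable.REQUIRED))
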