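"""Genotype data model: SNP definitions, unphased call matrices and I/O.

Genotype calls are stored unphased as one of four states per (sample, SNP):
homozygous major, heterozygous, homozygous minor, or missing.  Phase is never
read from input files — with standard genotyping assays it cannot be measured,
so any phase information is estimated downstream (see ``haplotype_em``).

Two on-disk formats are supported:

* VCF 4.x (biallelic records only), read through :mod:`cyvcf2`; REF is mapped
  to the major allele and ALT to the minor allele.
* a simple genotype CSV dialect with header ``sample,<snp1>,<snp2>,...`` and
  two-letter cells in allele letters (e.g. ``AG``); ``--`` marks a missing
  call.  Letter order within a cell is not meaningful (unphased).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HOM_MAJOR",
    "HET",
    "HOM_MINOR",
    "MISSING",
    "SNPDef",
    "GenotypeTable",
    "GenotypeCounts",
    "CohortLabels",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "genotype_counts",
    "allele_frequency",
    "ERAP2_SNPS",
    "ERAP2_SNP_IDS",
]

# Integer codes for the four call states (HOM_MAJOR/HET/HOM_MINOR count
# copies of the minor allele; MISSING is kept out of all statistics).
HOM_MAJOR: int = 0
HET: int = 1
HOM_MINOR: int = 2
MISSING: int = -1

_BASES = frozenset("ACGT")


class GenotypeParseError(ValueError):
    """Malformed genotype input; the message names the offending line/record."""


@dataclass(frozen=True)
class SNPDef:
    """A biallelic SNP with a fixed major/minor allele assignment.

    ``chrom``/``pos`` are optional and only used when writing VCF.
    """

    id: str
    major_allele: str
    minor_allele: str
    chrom: str = "5"
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.major_allele not in _BASES or self.minor_allele not in _BASES:
            raise ValueError(
                f"{self.id}: alleles must be single bases in ACGT, "
                f"got {self.major_allele!r}/{self.minor_allele!r}"
            )
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.id}: major and minor allele are identical")

    def call_from_letters(self, cell: str) -> int:
        """Map a two-letter genotype cell (order-insensitive) to a call code."""
        if cell in ("--", "..", "NN", ""):
            return MISSING
        if len(cell) != 2:
            raise ValueError(f"{self.id}: genotype cell {cell!r} is not two letters")
        n_minor = 0
        for letter in cell:
            if letter == self.minor_allele:
                n_minor += 1
            elif letter != self.major_allele:
                raise ValueError(
                    f"{self.id}: allele {letter!r} not in "
                    f"{{{self.major_allele},{self.minor_allele}}}"
                )
        return n_minor

    def letters_from_call(self, call: int) -> str:
        if call == MISSING:
            return "--"
        if call == HOM_MAJOR:
            return self.major_allele * 2
        if call == HET:
            # fixed canonical order: major then minor
            return self.major_allele + self.minor_allele
        if call == HOM_MINOR:
            return self.minor_allele * 2
        raise ValueError(f"invalid call code {call}")


# The five ERAP2 SNPs in locus order, with the minor-allele assignments used
# throughout: rs2549782 minor G, rs2548538 minor T, rs2248374 minor A,
# rs2287988 minor G, rs1056893 minor C.  Under this assignment the two
# canonical five-SNP haplotypes are GTAGC (all-minor) and TAGAT (all-major).
ERAP2_SNPS: tuple[SNPDef, ...] = (
    SNPDef("rs2549782", major_allele="T", minor_allele="G", pos=1),
    SNPDef("rs2548538", major_allele="A", minor_allele="T", pos=2),
    SNPDef("rs2248374", major_allele="G", minor_allele="A", pos=3),
    SNPDef("rs2287988", major_allele="A", minor_allele="G", pos=4),
    SNPDef("rs1056893", major_allele="T", minor_allele="C", pos=5),
)
ERAP2_SNP_IDS: tuple[str, ...] = tuple(s.id for s in ERAP2_SNPS)


@dataclass
class GenotypeTable:
    """An n_samples x n_snps matrix of unphased genotype calls."""

    samples: list[str]
    snps: list[SNPDef]
    calls: np.ndarray  # int8, shape (n_samples, n_snps), codes above

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = [s.id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP id")
        bad = ~np.isin(self.calls, (HOM_MAJOR, HET, HOM_MINOR, MISSING))
        if bad.any():
            raise ValueError("invalid call codes in matrix")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def snp(self, snp_id: str) -> SNPDef:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> np.ndarray:
        return self.calls[:, self.snp_index(snp_id)]

    def minor_dosage(self, snp_id: str) -> np.ndarray:
        """Minor-allele dosage per sample (float, NaN where missing)."""
        col = self.column(snp_id).astype(float)
        col[col == MISSING] = np.nan
        return col

    def sample_indices(self, subset: Iterable[str] | None) -> np.ndarray:
        if subset is None:
            return np.arange(self.n_samples)
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = []
        for s in subset:
            if s not in lookup:
                raise KeyError(f"unknown sample id {s!r}")
            idx.append(lookup[s])
        if not idx:
            raise ValueError("empty sample subset")
        return np.asarray(sorted(idx))

    def subset(self, sample_ids: Sequence[str]) -> "GenotypeTable":
        idx = self.sample_indices(sample_ids)
        return GenotypeTable(
            [self.samples[i] for i in idx], list(self.snps), self.calls[idx]
        )

    # -- writers -----------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the genotype CSV dialect (two-letter cells, '--' missing)."""
        with open(path, "w") as fh:
            fh.write("sample," + ",".join(self.snp_ids) + "\n")
            for i, sample in enumerate(self.samples):
                cells = [
                    snp.letters_from_call(int(self.calls[i, j]))
                    for j, snp in enumerate(self.snps)
                ]
                fh.write(sample + "," + ",".join(cells) + "\n")

    def to_vcf(self, path: str | Path) -> None:
        """Write a minimal VCF 4.2 with REF=major, ALT=minor, GT-only FORMAT."""
        gt_map = {HOM_MAJOR: "0/0", HET: "0/1", HOM_MINOR: "1/1", MISSING: "./."}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=erap2hap\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for j, snp in enumerate(self.snps):
                pos = snp.pos if snp.pos is not None else j + 1
                gts = "\t".join(gt_map[int(c)] for c in self.calls[:, j])
                fh.write(
                    f"{snp.chrom}\t{pos}\t{snp.id}\t{snp.major_allele}\t"
                    f"{snp.minor_allele}\t.\tPASS\t.\tGT\t{gts}\n"
                )


@dataclass(frozen=True)
class GenotypeCounts:
    """Per-SNP genotype counts over non-missing calls (plus missing tally)."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor, self.n_missing) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    @property
    def n_samples(self) -> int:
        return self.n_typed + self.n_missing

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_hom_minor + self.n_het

    @property
    def major_allele_count(self) -> int:
        return 2 * self.n_hom_major + self.n_het

    def as_array(self) -> np.ndarray:
        return np.array([self.n_hom_major, self.n_het, self.n_hom_minor])


@dataclass
class CohortLabels:
    """Case/control status and cohort stratum (maternal/fetal) per sample."""

    status: dict[str, str]  # sample -> "case" | "control"
    stratum: dict[str, str]  # sample -> "maternal" | "fetal"

    def __post_init__(self) -> None:
        for s, v in self.status.items():
            if v not in ("case", "control"):
                raise ValueError(f"sample {s!r}: status must be case/control, got {v!r}")
        for s, v in self.stratum.items():
            if v not in ("maternal", "fetal"):
                raise ValueError(
                    f"sample {s!r}: stratum must be maternal/fetal, got {v!r}"
                )

    def validate_against(self, table: GenotypeTable) -> None:
        known = set(table.samples)
        missing = [s for s in self.status if s not in known]
        if missing:
            raise ValueError(f"labeled samples absent from genotype table: {missing[:5]}")

    def cases(self) -> list[str]:
        return [s for s, v in self.status.items() if v == "case"]

    def controls(self) -> list[str]:
        return [s for s, v in self.status.items() if v == "control"]

    def in_stratum(self, stratum: str) -> list[str]:
        return [s for s, v in self.stratum.items() if v == stratum]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample,status,stratum\n")
            for s in self.status:
                fh.write(f"{s},{self.status[s]},{self.stratum.get(s, 'fetal')}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortLabels":
        status: dict[str, str] = {}
        stratum: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header[:3] != ["sample", "status", "stratum"]:
                raise GenotypeParseError(
                    f"{path}: expected header sample,status,stratum"
                )
            for lineno, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) < 3:
                    raise GenotypeParseError(f"{path}:{lineno}: expected 3 fields")
                status[parts[0]] = parts[1]
                stratum[parts[0]] = parts[2]
        return cls(status, stratum)


# ---------------------------------------------------------------------------
# readers


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    snp_defs: Sequence[SNPDef] | None = None,
) -> GenotypeTable:
    """Read a genotype table from VCF or the genotype CSV dialect.

    ``format`` is inferred from the file extension when not given.  For CSV,
    ``snp_defs`` fixes the major/minor assignment of each column; when absent
    the more frequent allele in the file is taken as major (ties broken
    alphabetically).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz", ".bcf") else "csv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "csv":
        return _read_csv(path, snp_defs)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(table: GenotypeTable, path: str | Path, format: str = "csv") -> None:
    if format == "csv":
        table.to_csv(path)
    elif format == "vcf":
        table.to_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeTable:
    from cyvcf2 import VCF  # local import: only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps: list[SNPDef] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for record in vcf:
        if len(record.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {record.CHROM}:{record.POS} is multi-allelic "
                f"(ALT={','.join(record.ALT)}); only biallelic SNPs are supported"
            )
        ref, alt = record.REF, record.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            raise GenotypeParseError(
                f"{path}: record {record.CHROM}:{record.POS} is not a SNP "
                f"(REF={ref}, ALT={alt})"
            )
        snp_id = record.ID if record.ID not in (None, ".") else f"{record.CHROM}:{record.POS}"
        if snp_id in seen:
            raise GenotypeParseError(f"{path}: duplicate SNP id {snp_id!r}")
        seen.add(snp_id)
        snps.append(
            SNPDef(snp_id, major_allele=ref, minor_allele=alt,
                   chrom=record.CHROM, pos=record.POS)
        )
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(record.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                col[i] = MISSING
            else:
                col[i] = a + b  # 0/0 -> 0, 0/1 -> 1, 1/1 -> 2
        columns.append(col)
    if not snps:
        raise GenotypeParseError(f"{path}: no usable records")
    return GenotypeTable(samples, snps, np.column_stack(columns))


def _read_csv(path: Path, snp_defs: Sequence[SNPDef] | None) -> GenotypeTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("sample"):
            raise GenotypeParseError(f"{path}:1: header must start with 'sample'")
        snp_ids = header.split(",")[1:]
        if len(set(snp_ids)) != len(snp_ids):
            raise GenotypeParseError(f"{path}:1: duplicate SNP id in header")
        rows: list[tuple[str, list[str]]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != len(snp_ids) + 1:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(snp_ids) + 1} fields, "
                    f"got {len(parts)}"
                )
            rows.append((parts[0], parts[1:]))

    if snp_defs is not None:
        defs = {d.id: d for d in snp_defs}
        missing_defs = [s for s in snp_ids if s not in defs]
        if missing_defs:
            raise GenotypeParseError(
                f"{path}: no SNPDef provided for columns {missing_defs}"
            )
        snps = [defs[s] for s in snp_ids]
    else:
        snps = _infer_snp_defs(path, snp_ids, rows)

    calls = np.full((len(rows), len(snp_ids)), MISSING, dtype=np.int8)
    for i, (sample, cells) in enumerate(rows):
        for j, cell in enumerate(cells):
            try:
                calls[i, j] = snps[j].call_from_letters(cell.strip().upper())
            except ValueError as exc:
                raise GenotypeParseError(f"{path}:{i + 2}: {exc}") from None
    return GenotypeTable([r[0] for r in rows], snps, calls)


def _infer_snp_defs(
    path: Path, snp_ids: list[str], rows: list[tuple[str, list[str]]]
) -> list[SNPDef]:
    snps = []
    for j, snp_id in enumerate(snp_ids):
        tally: dict[str, int] = {}
        for _, cells in rows:
            cell = cells[j].strip().upper()
            if cell in ("--", "..", "NN", ""):
                continue
            for letter in cell:
                if letter not in _BASES:
                    raise GenotypeParseError(
                        f"{path}: column {snp_id}: invalid allele {letter!r}"
                    )
                tally[letter] = tally.get(letter, 0) + 1
        if len(tally) > 2:
            raise GenotypeParseError(
                f"{path}: column {snp_id} has more than two alleles {sorted(tally)}"
            )
        if not tally:
            raise GenotypeParseError(f"{path}: column {snp_id} has no typed calls")
        if len(tally) == 1:
            # monomorphic column: pick an arbitrary distinct minor letter
            major = next(iter(tally))
            minor = "A" if major != "A" else "C"
        else:
            (a1, n1), (a2, n2) = sorted(tally.items())
            major, minor = (a1, a2) if n1 >= n2 else (a2, a1)
        snps.append(SNPDef(snp_id, major_allele=major, minor_allele=minor))
    return snps


# ---------------------------------------------------------------------------
# counting


def genotype_counts(
    table: GenotypeTable, snp: str, subset: Iterable[str] | None = None
) -> GenotypeCounts:
    """Genotype counts for one SNP over the (optionally subset) cohort.

    Missing calls are excluded from the three genotype classes and tallied
    separately (pairwise deletion).
    """
    idx = table.sample_indices(subset)
    col = table.column(snp)[idx]
    counts = GenotypeCounts(
        int((col == HOM_MAJOR).sum()),
        int((col == HET).sum()),
        int((col == HOM_MINOR).sum()),
        int((col == MISSING).sum()),
    )
    if counts.n_typed == 0:
        raise ValueError(f"{snp}: no non-missing calls in the requested subset")
    return counts


def allele_frequency(counts: GenotypeCounts) -> float:
    """Minor-allele frequency from genotype counts: (2*hom_minor + het) / 2n."""
    if counts.n_typed == 0:
        raise ValueError("no non-missing calls: allele frequency undefined")
    return counts.minor_allele_count / (2 * counts.n_typed)
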