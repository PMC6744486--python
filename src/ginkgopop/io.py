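"""File formats: minimal VCF 4.2 (GT only), population map TSV, distance
matrices, window tables and Q/eigenvector tables.

The VCF subset written here has placeholder REF/ALT alleles (A/T) and a
single GT FORMAT field; positions are 1-based.  The reader accepts exactly
this subset (plus arbitrary extra header lines) and reports malformed
input with line numbers.  Multi-allelic records are skipped (counted) or
rejected per flag.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .stats import DistanceMatrix

__all__ = [
    "VcfFormatError",
    "write_vcf",
    "read_vcf",
    "write_popmap",
    "read_popmap",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_table",
    "file_digest",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_CODE_GT = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": MISSING, ".|.": MISSING, ".": MISSING,
}


class VcfFormatError(ValueError):
    """Malformed VCF input; the message carries the offending line number."""


def write_vcf(G: GenotypeMatrix, path: str | Path, source: str = "ginkgopop") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(G.chroms):
            length = G.chrom_lengths.get(chrom)
            if length:
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(G.samples) + "\n")
        for s in range(G.n_sites):
            gts = "\t".join(_GT_CODE[int(g)] for g in G.genotypes[:, s])
            fh.write(
                f"{G.chroms[s]}\t{G.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(
    path: str | Path,
    popmap: dict[str, str] | None = None,
    multiallelic: str = "skip",
) -> GenotypeMatrix:
    """Read a biallelic-SNP GT matrix from a minimal VCF 4.2 file.

    ``multiallelic="skip"`` drops records with more than one ALT allele and
    counts them on the returned matrix (``n_multiallelic_skipped``);
    ``"error"`` raises instead.
    """
    if multiallelic not in ("skip", "error"):
        raise ValueError("multiallelic must be 'skip' or 'error'")
    path = Path(path)
    samples: list[str] | None = None
    chrom_lengths: dict[str, int] = {}
    genos: list[list[int]] = []
    positions: list[int] = []
    chroms: list[str] = []
    n_skipped = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1 and not line.startswith("##fileformat=VCF"):
                    raise VcfFormatError(f"line 1: missing ##fileformat header")
                if line.startswith("##contig=<"):
                    body = line[len("##contig=<"):].rstrip(">")
                    kv = dict(
                        item.split("=", 1) for item in body.split(",") if "=" in item
                    )
                    if "ID" in kv and "length" in kv:
                        chrom_lengths[kv["ID"]] = int(kv["length"])
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if fields[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                    "INFO", "FORMAT",
                ]:
                    raise VcfFormatError(f"line {lineno}: malformed column header")
                samples = fields[9:]
                if not samples:
                    raise VcfFormatError(f"line {lineno}: VCF has no sample columns")
                continue
            if samples is None:
                raise VcfFormatError(f"line {lineno}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise VcfFormatError(
                    f"line {lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            chrom, pos, _id, _ref, alt, _q, _f, _info, fmt = fields[:9]
            if "," in alt:
                if multiallelic == "error":
                    raise VcfFormatError(f"line {lineno}: multi-allelic record")
                n_skipped += 1
                continue
            try:
                pos_i = int(pos)
            except ValueError:
                raise VcfFormatError(f"line {lineno}: non-integer POS {pos!r}") from None
            if not fmt.split(":")[0] == "GT":
                raise VcfFormatError(f"line {lineno}: FORMAT must begin with GT")
            row = []
            for col, cell in enumerate(fields[9:]):
                gt = cell.split(":")[0]
                if gt not in _CODE_GT:
                    raise VcfFormatError(
                        f"line {lineno}: unparseable genotype {gt!r} "
                        f"(sample {samples[col]})"
                    )
                row.append(_CODE_GT[gt])
            if all(g == MISSING for g in row):
                continue  # no non-missing call: site not retained
            genos.append(row)
            positions.append(pos_i)
            chroms.append(chrom)
    if samples is None:
        raise VcfFormatError("no #CHROM header found")
    geno = (
        np.array(genos, dtype=np.int8).T
        if genos
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    G = GenotypeMatrix(
        geno,
        np.array(positions, dtype=np.int64),
        np.array(chroms, dtype=object),
        samples,
        dict(popmap or {}),
        chrom_lengths,
    )
    G.n_multiallelic_skipped = n_skipped  # type: ignore[attr-defined]
    return G


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def write_popmap(popmap: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{s}\t{p}\n" for s, p in popmap.items())
    )


def read_popmap(
    path: str | Path,
    vcf_samples: list[str] | None = None,
    strict: bool = True,
    default_pop: str = "UNASSIGNED",
) -> dict[str, str]:
    """sample_id<TAB>population, CRLF- and trailing-whitespace-tolerant.

    With ``vcf_samples`` given, strict mode rejects VCF samples missing
    from the map; non-strict mode groups them under ``default_pop``.
    """
    popmap: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}: line {lineno}: expected sample<TAB>population")
        sid, pop = parts[0].strip(), parts[1].strip()
        if sid in popmap:
            raise ValueError(f"{path}: line {lineno}: duplicate sample id {sid!r}")
        popmap[sid] = pop
    if vcf_samples is not None:
        missing = [s for s in vcf_samples if s not in popmap]
        if missing and strict:
            raise ValueError(
                f"samples missing from population map: {', '.join(missing[:5])}"
                + ("..." if len(missing) > 5 else "")
            )
        for s in missing:
            popmap[s] = default_pop
    return popmap


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

def write_distance_matrix(D: DistanceMatrix, path: str | Path, header: str = "") -> None:
    """Square matrix TSV with id header row and column."""
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("sample\t" + "\t".join(D.samples) + "\n")
        for i, s in enumerate(D.samples):
            fh.write(s + "\t" + "\t".join(f"{v:.8g}" for v in D.values[i]) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float)
    samples = list(df.columns)
    m = np.zeros_like(values, dtype=np.int64)
    return DistanceMatrix(samples, values, m)


def write_table(df: pd.DataFrame, path: str | Path, header: str = "") -> None:
    """TSV with an optional leading '#' comment naming producer and seed."""
    with Path(path).open("w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
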