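"""PLINK text (PED/MAP) and binary (BED/BIM/FAM) genotype I/O.

Both dialects are mapped onto :class:`~rohscan.datamodel.GenotypeMatrix`.
Coordinates are 1-based inclusive internally; BED gene annotation input
(0-based half-open) is shifted on read.  Non-autosomal and unmapped markers
(chromosome "0", X/Y/MT and friends) are dropped at load with a logged count.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import MISSING, FormatError, GenotypeMatrix, IntegrityError

logger = logging.getLogger(__name__)

BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

#: 2-bit BED code -> internal call (00 hom A1, 01 missing, 10 het, 11 hom A2)
_BED_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
#: internal call -> 2-bit BED code, indexed by call + 1 (missing first)
_BED_ENCODE = np.array([1, 0, 2, 3], dtype=np.uint8)

_NON_AUTOSOMAL = {"0", "X", "Y", "XY", "MT", "M", "23", "24", "25", "26"}


def _is_autosome(label: str) -> bool:
    return str(label) not in _NON_AUTOSOMAL


def _drop_non_autosomal(markers: pd.DataFrame, calls: np.ndarray):
    keep = markers["chromosome"].astype(str).map(_is_autosome).to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d non-autosomal/unmapped markers at load", n_drop)
        markers = markers.loc[keep].reset_index(drop=True)
        calls = calls[:, keep]
    return markers, calls


def _read_bim(bim_path) -> pd.DataFrame:
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele_a", "allele_b"],
        dtype={"chromosome": str, "marker_id": str, "allele_a": str, "allele_b": str},
    )
    return bim[["marker_id", "chromosome", "position_bp", "allele_a", "allele_b"]]


def _read_fam(fam_path) -> pd.DataFrame:
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["family_id", "sample_id", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    fam["population"] = fam["family_id"]
    return fam[["sample_id", "population", "family_id", "father", "mother", "sex", "phenotype"]]


def read_plink_binary(bed_path, bim_path, fam_path, keep_non_autosomal=False) -> GenotypeMatrix:
    """Read a PLINK BED/BIM/FAM trio (SNP-major layout)."""
    markers = _read_bim(bim_path)
    samples = _read_fam(fam_path)
    n, m = len(samples), len(markers)
    raw = Path(bed_path).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise FormatError(f"{bed_path}: bad BED magic bytes {raw[:3].hex()}")
    bytes_per_marker = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != m * bytes_per_marker:
        raise IntegrityError(
            f"{bed_path}: payload is {payload.size} bytes, expected "
            f"{m * bytes_per_marker} for {n} samples x {m} markers"
        )
    rows = payload.reshape(m, bytes_per_marker)
    two_bit = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
    for k in range(4):  # sample index increases from the low bits of each byte
        two_bit[:, k::4] = (rows >> (2 * k)) & 0b11
    calls = _BED_DECODE[two_bit[:, :n]].T.copy()
    if not keep_non_autosomal:
        markers, calls = _drop_non_autosomal(markers, calls)
    return GenotypeMatrix(calls, samples, markers)


def write_plink_binary(g: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    """Write a GenotypeMatrix as a BED/BIM/FAM trio (SNP-major)."""
    n, m = g.n_samples, g.n_markers
    bim = pd.DataFrame(
        {
            "chromosome": g.markers["chromosome"],
            "marker_id": g.markers["marker_id"],
            "cm": 0,
            "position_bp": g.markers["position_bp"],
            "allele_a": g.markers["allele_a"],
            "allele_b": g.markers["allele_b"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    s = g.samples
    fam = pd.DataFrame(
        {
            "family_id": s["family_id"] if "family_id" in s else s["population"],
            "sample_id": s["sample_id"],
            "father": s["father"] if "father" in s else "0",
            "mother": s["mother"] if "mother" in s else "0",
            "sex": s["sex"] if "sex" in s else "0",
            "phenotype": s["phenotype"] if "phenotype" in s else "-9",
        }
    )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)

    bytes_per_marker = (n + 3) // 4
    codes = _BED_ENCODE[g.calls.T.astype(np.int16) + 1].astype(np.uint8)  # (m, n)
    padded = np.zeros((m, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_marker), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink_text(ped_path, map_path, keep_non_autosomal=False) -> GenotypeMatrix:
    """Read a PLINK PED/MAP pair.

    Allele labels per marker are inferred from the data (lexicographically:
    ``allele_a`` = smaller label); the pair "0 0" codes a missing call and
    allele order within a genotype is unordered (``A T`` == ``T A``).
    """
    mp = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp"],
        dtype={"chromosome": str, "marker_id": str},
    )
    m = len(mp)
    sample_rows = []
    geno_rows = []
    expected = 6 + 2 * m
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != expected:
                raise FormatError(
                    f"{ped_path}:{ln}: {len(fields)} fields, expected {expected}"
                )
            sample_rows.append(fields[:6])
            geno_rows.append(fields[6:])
    samples = pd.DataFrame(
        sample_rows,
        columns=["family_id", "sample_id", "father", "mother", "sex", "phenotype"],
    )
    samples["population"] = samples["family_id"]
    samples = samples[
        ["sample_id", "population", "family_id", "father", "mother", "sex", "phenotype"]
    ]

    n = len(samples)
    alleles = np.array(geno_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        col = alleles[:, j, :]
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if len(observed) > 2:
            raise FormatError(
                f"{ped_path}: marker {mp['marker_id'].iat[j]} has >2 alleles {observed}"
            )
        a = observed[0] if observed else "0"
        b = observed[1] if len(observed) > 1 else "0"
        allele_a[j], allele_b[j] = a, b
        for i in range(n):
            x, y = col[i]
            if x == "0" or y == "0":
                continue  # half-missing treated as missing
            calls[i, j] = (x == b) + (y == b)
    markers = pd.DataFrame(
        {
            "marker_id": mp["marker_id"],
            "chromosome": mp["chromosome"],
            "position_bp": mp["position_bp"],
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    if not keep_non_autosomal:
        markers, calls = _drop_non_autosomal(markers, calls)
    return GenotypeMatrix(calls, samples, markers)


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    mp = pd.DataFrame(
        {
            "chromosome": g.markers["chromosome"],
            "marker_id": g.markers["marker_id"],
            "cm": 0,
            "position_bp": g.markers["position_bp"],
        }
    )
    mp.to_csv(map_path, sep="\t", header=False, index=False)
    a = g.markers["allele_a"].to_numpy()
    b = g.markers["allele_b"].to_numpy()
    s = g.samples
    with open(ped_path, "w") as fh:
        for i in range(g.n_samples):
            meta = [
                str(s["family_id"].iat[i]) if "family_id" in s else str(s["population"].iat[i]),
                str(s["sample_id"].iat[i]),
                str(s["father"].iat[i]) if "father" in s else "0",
                str(s["mother"].iat[i]) if "mother" in s else "0",
                str(s["sex"].iat[i]) if "sex" in s else "0",
                str(s["phenotype"].iat[i]) if "phenotype" in s else "-9",
            ]
            pairs = []
            for j, c in enumerate(g.calls[i]):
                if c == MISSING:
                    pairs.append("0 0")
                elif c == 0:
                    pairs.append(f"{a[j]} {a[j]}")
                elif c == 1:
                    pairs.append(f"{a[j]} {b[j]}")
                else:
                    pairs.append(f"{b[j]} {b[j]}")
            fh.write(" ".join(meta) + " " + " ".join(pairs) + "\n")


def read_populations(path) -> pd.DataFrame:
    """Two-column whitespace file: sample_id, population."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["sample_id", "population"], dtype=str
    )
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


def assign_populations(g: GenotypeMatrix, populations: pd.DataFrame) -> GenotypeMatrix:
    """Attach breed labels from a population file, replacing FAM-derived ones."""
    mapping = dict(zip(populations["sample_id"], populations["population"]))
    missing = [s for s in g.sample_ids if s not in mapping]
    if missing:
        raise IntegrityError(f"samples without population assignment: {missing[:5]}")
    samples = g.samples.copy()
    samples["population"] = samples["sample_id"].map(mapping)
    return GenotypeMatrix(g.calls.copy(), samples, g.markers)


def read_gene_annotation(path, fmt: str) -> pd.DataFrame:
    """Read gene intervals from BED4 (0-based half-open) or GFF3 (1-based).

    Returns a DataFrame with ``name, chromosome, start_bp, end_bp`` columns,
    1-based inclusive, sorted by genome position.
    """
    fmt = fmt.lower()
    if fmt == "bed":
        try:
            df = pd.read_csv(
                path,
                sep=r"\s+",
                header=None,
                comment="#",
                usecols=[0, 1, 2, 3],
                names=["chromosome", "start", "end", "name"],
                dtype={"chromosome": str, "name": str},
            )
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=["name", "chromosome", "start_bp", "end_bp"])
        out = pd.DataFrame(
            {
                "name": df["name"],
                "chromosome": df["chromosome"],
                "start_bp": df["start"].astype(np.int64) + 1,
                "end_bp": df["end"].astype(np.int64),
            }
        )
    elif fmt == "gff3":
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2].lower() != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID", "")
                name = name.removeprefix("gene:")
                rows.append((name, f[0], int(f[3]), int(f[4])))
        out = pd.DataFrame(rows, columns=["name", "chromosome", "start_bp", "end_bp"])
    else:
        raise ValueError(f"unknown annotation format {fmt!r} (expected 'bed' or 'gff3')")
    if (out["start_bp"] > out["end_bp"]).any():
        raise FormatError(f"{path}: gene interval with start > end")
    return out.sort_values(
        ["chromosome", "start_bp"], key=lambda s: s.map(str) if s.name == "chromosome" else s
    ).reset_index(drop=True)
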