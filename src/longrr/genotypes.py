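"""SNP dosage handling: readers, quality control, imputation and the genomic
relationship matrix (GRM).

Dosages count copies of the A1 allele (0, 1 or 2); missing calls are stored
as NaN.  Two on-disk dialects are supported: a plain CSV (first column
accession ID, header row of marker IDs, missing coded ``NA``) and the PLINK 1
binary trio (.bed/.bim/.fam, SNP-major).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "GenomicRelationship",
    "read_genotypes",
    "write_plink",
    "qc_filter",
    "impute_mean",
    "compute_grm",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# PLINK 1 two-bit codes in SNP-major order: 00 hom A1, 01 missing, 10 het,
# 11 hom A2.  Dosage counts A1 alleles.
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


@dataclass(frozen=True)
class MarkerMatrix:
    """Accession x marker dosage table with NaN marking missing calls."""

    dosages: np.ndarray
    accession_ids: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self):
        dos = np.asarray(self.dosages, dtype=float)
        acc = np.asarray(self.accession_ids)
        mrk = np.asarray(self.marker_ids)
        if dos.ndim != 2 or dos.shape != (acc.size, mrk.size):
            raise ValueError(
                f"dosage shape {dos.shape} does not match "
                f"{acc.size} accessions x {mrk.size} markers"
            )
        if len(set(acc.tolist())) != acc.size:
            raise ValueError("duplicate accession IDs")
        if len(set(mrk.tolist())) != mrk.size:
            raise ValueError("duplicate marker IDs")
        # post-imputation matrices carry fractional dosages; only reject
        # integer-valued entries outside {0,1,2}
        bad = ~np.isnan(dos) & (dos == np.round(dos)) & ~np.isin(dos, (0.0, 1.0, 2.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage {dos[i, j]} at accession {acc[i]!r}, marker {mrk[j]!r} "
                "is not in {0, 1, 2}"
            )
        if ((dos < 0) | (dos > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        object.__setattr__(self, "dosages", dos)
        object.__setattr__(self, "accession_ids", acc)
        object.__setattr__(self, "marker_ids", mrk)

    @property
    def n_accessions(self) -> int:
        return self.accession_ids.size

    @property
    def n_markers(self) -> int:
        return self.marker_ids.size

    def call_rate(self) -> np.ndarray:
        """Per-marker fraction of non-missing calls."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.accession_ids, columns=self.marker_ids)


@dataclass(frozen=True)
class GenomicRelationship:
    """VanRaden-style genomic relationship matrix G = W_sc W_sc' / p."""

    G: np.ndarray
    accession_ids: np.ndarray
    n_markers: int = 0
    ridge: float = 0.0

    def __post_init__(self):
        G = np.asarray(self.G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("G must be square")
        if not np.allclose(G, G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "accession_ids", np.asarray(self.accession_ids))

    def subset(self, idx: np.ndarray) -> "GenomicRelationship":
        idx = np.asarray(idx)
        return GenomicRelationship(
            self.G[np.ix_(idx, idx)], self.accession_ids[idx], self.n_markers, self.ridge
        )


def read_genotypes(path, format: str = "csv") -> MarkerMatrix:
    """Read a dosage table from ``csv`` or ``plink-bed``.

    For ``plink-bed`` the path may be the ``.bed`` file or the common prefix
    of the .bed/.bim/.fam trio.
    """
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "plink-bed":
        return _read_plink(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_csv(path: Path) -> MarkerMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty genotype file") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no marker columns found")
    vals = df.to_numpy(dtype=float)
    bad = ~np.isnan(vals) & ~np.isin(vals, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: invalid dosage {vals[i, j]} for accession {df.index[i]!r}, "
            f"marker {df.columns[j]!r}"
        )
    return MarkerMatrix(vals, df.index.to_numpy(), df.columns.to_numpy())


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix == ".bed" else path


def _read_plink(path: Path) -> MarkerMatrix:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None)
    accession_ids = fam_df.iloc[:, 1].to_numpy()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None)
    marker_ids = bim_df.iloc[:, 1].to_numpy()
    n, p = accession_ids.size, marker_ids.size

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{bed}: not a SNP-major PLINK 1 .bed file")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * p:
        raise ValueError(
            f"{bed}: expected {bytes_per_snp * p} data bytes for {n} samples x "
            f"{p} SNPs, found {body.size}"
        )
    blocks = body.reshape(p, bytes_per_snp)
    # unpack two-bit genotype codes, little-endian within each byte
    shifts = np.arange(4) * 2
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T
    return MarkerMatrix(dosages, accession_ids, marker_ids)


def write_plink(markers: MarkerMatrix, prefix) -> None:
    """Write a MarkerMatrix as a PLINK 1 .bed/.bim/.fam trio (SNP-major)."""
    prefix = Path(prefix)
    dos = markers.dosages
    if not np.all(np.isnan(dos) | np.isin(dos, (0.0, 1.0, 2.0))):
        raise ValueError("PLINK output requires integer dosages (write before imputation)")
    n, p = dos.shape
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for acc in markers.accession_ids:
            fh.write(f"{acc} {acc} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, mid in enumerate(markers.marker_ids):
            fh.write(f"1 {mid} 0 {j + 1} A G\n")
    code = np.full((p, n), 0b01, dtype=np.uint8)
    dT = dos.T
    code[dT == 2.0] = 0b00
    code[dT == 1.0] = 0b10
    code[dT == 0.0] = 0b11
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.full((p, pad), 0b01, dtype=np.uint8)], axis=1)
    quads = code.reshape(p, -1, 4)
    shifts = np.arange(4) * 2
    packed = (quads << shifts[None, None, :]).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)


def qc_filter(
    markers: MarkerMatrix, min_call_rate: float = 0.95, min_maf: float = 0.05
) -> MarkerMatrix:
    """Retain markers with call rate > ``min_call_rate`` and MAF > ``min_maf``.

    Both comparisons are strict, so markers sitting exactly on a threshold
    are removed.  The accession set is never altered.
    """
    if not (0 <= min_call_rate <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    keep = (markers.call_rate() > min_call_rate) & (markers.maf() > min_maf)
    if not keep.any():
        warnings.warn("qc_filter removed every marker", stacklevel=2)
    return MarkerMatrix(
        markers.dosages[:, keep], markers.accession_ids, markers.marker_ids[keep]
    )


def impute_mean(markers: MarkerMatrix) -> MarkerMatrix:
    """Replace missing calls by the per-marker mean dosage."""
    dos = markers.dosages
    missing = np.isnan(dos)
    if not missing.any():
        return markers
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = markers.marker_ids[all_missing]
        raise ValueError(
            f"markers with no observed calls (run qc_filter first): {bad[:5].tolist()}"
        )
    col_means = np.nanmean(dos, axis=0)
    out = np.where(missing, col_means[None, :], dos)
    return MarkerMatrix(out, markers.accession_ids, markers.marker_ids)


def compute_grm(
    markers: MarkerMatrix, ridge: float = 1e-6, ddof: int = 0
) -> GenomicRelationship:
    """G = W_sc W_sc' / p with columns centered and scaled to unit variance.

    The standardization divisor defaults to the population SD (``ddof=0``),
    under which mean(diag(G)) = 1 exactly.  A small ridge is added to the
    diagonal so that training-set blocks of G stay invertible downstream.
    """
    dos = markers.dosages
    if np.isnan(dos).any():
        raise ValueError("missing dosages present; run impute_mean first")
    mu = dos.mean(axis=0)
    sd = dos.std(axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        raise ValueError(
            f"zero-variance (monomorphic) markers: {markers.marker_ids[zero][:5].tolist()}"
        )
    W = (dos - mu) / sd
    G = W @ W.T / markers.n_markers
    G = (G + G.T) / 2.0
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return GenomicRelationship(G, markers.accession_ids, markers.n_markers, ridge)
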