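"""Barcode extraction and error-correcting assignment from FASTQ reads.

Each amplicon read carries a constant anchor, the 20-nt barcode, and a second
anchor. Extraction locates the first offset where both anchors match within a
mismatch budget and takes the bases between them; assignment finds the unique
library barcode within the decoding radius of the candidate (bounded-distance
decoding). Because the barcode code has minimum pairwise Hamming distance d,
any candidate with at most floor((d−1)/2) substitutions has exactly one
codeword that close, so error correction can never silently cross-assign.

Reads that fail extraction or have no codeword within the radius are tallied
as unassigned; candidates with two codewords tied at the minimum qualifying
distance are tallied as ambiguous and excluded from counts. Every read lands
in exactly one of {a barcode, unassigned, ambiguous} — the conservation
invariant checked on every run.

Internally both steps are vectorized over numpy byte matrices; the public
per-read functions share the same code path as the bulk counter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcode_design import BarcodeSet, max_correctable_errors

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic_data import LibraryDesign

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class DecodeParams:
    """Decoding policy for a counting run.

    max_errors: barcode substitutions corrected; ``None`` defaults to the
    code's unique-decoding radius floor((d−1)/2).
    anchor_mismatch_budget: mismatches tolerated in each anchor.
    revcomp_rescue: retry unextracted reads on the reverse complement.
    """

    max_errors: int | None = None
    anchor_mismatch_budget: int = 1
    revcomp_rescue: bool = False


@dataclass
class ScreenCounts:
    """Per-(lineage, fraction) barcode read counts with routing tallies."""

    counts: dict[tuple[str, str], dict[str, int]]
    unassigned: dict[tuple[str, str], int]
    ambiguous: dict[tuple[str, str], int]
    total_reads: dict[tuple[str, str], int]

    def check_conservation(self) -> None:
        """Assert assigned + unassigned + ambiguous = total for every file."""
        for key, per_bc in self.counts.items():
            assigned = sum(per_bc.values())
            total = assigned + self.unassigned[key] + self.ambiguous[key]
            if total != self.total_reads[key]:
                raise AssertionError(
                    f"read conservation violated for {key}: "
                    f"{assigned}+{self.unassigned[key]}+{self.ambiguous[key]} "
                    f"!= {self.total_reads[key]}"
                )

    def assignment_rate(self, lineage: str, fraction: str) -> float:
        key = (lineage, fraction)
        total = self.total_reads[key]
        if total == 0:
            return float("nan")
        return sum(self.counts[key].values()) / total

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"lineage": lin, "fraction": frac, "barcode_id": b, "count": c}
            for (lin, frac), per_bc in self.counts.items()
            for b, c in per_bc.items()
        ]
        return pd.DataFrame(rows, columns=["lineage", "fraction", "barcode_id", "count"])

    def qc_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.counts:
            lin, frac = key
            rows.append(
                {
                    "lineage": lin,
                    "fraction": frac,
                    "total_reads": self.total_reads[key],
                    "assigned": sum(self.counts[key].values()),
                    "unassigned": self.unassigned[key],
                    "ambiguous": self.ambiguous[key],
                    "assignment_rate": self.assignment_rate(lin, frac),
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, counts_path: str | Path, qc_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index=False)
        if qc_path is not None:
            self.qc_frame().to_csv(qc_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, counts_path: str | Path, qc_path: str | Path
    ) -> "ScreenCounts":
        cdf = pd.read_csv(counts_path, sep="\t")
        qdf = pd.read_csv(qc_path, sep="\t")
        counts: dict[tuple[str, str], dict[str, int]] = {}
        for (lin, frac), grp in cdf.groupby(["lineage", "fraction"], sort=False):
            counts[(lin, frac)] = dict(
                zip(grp["barcode_id"].astype(str), grp["count"].astype(int))
            )
        unassigned, ambiguous, total = {}, {}, {}
        for _, row in qdf.iterrows():
            key = (str(row["lineage"]), str(row["fraction"]))
            counts.setdefault(key, {})
            unassigned[key] = int(row["unassigned"])
            ambiguous[key] = int(row["ambiguous"])
            total[key] = int(row["total_reads"])
        return cls(counts=counts, unassigned=unassigned, ambiguous=ambiguous, total_reads=total)


# ---------------------------------------------------------------------------
# extraction


def _to_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def extract_barcode(
    read: str,
    anchor5: str,
    anchor3: str,
    barcode_length: int,
    anchor_mismatch_budget: int = 1,
) -> str | None:
    """Pull the barcode out of one read, or ``None`` if no anchor context fits.

    Scans offsets left to right; the first offset where anchor5 matches
    within the budget AND anchor3 matches within the budget immediately after
    the barcode wins.
    """
    if len(read) < len(anchor5) + barcode_length + len(anchor3):
        return None
    mat = _to_bytes(read)[None, :]
    cand, ok = _extract_matrix(
        mat, anchor5, anchor3, barcode_length, anchor_mismatch_budget
    )
    if not ok[0]:
        return None
    return cand[0].tobytes().decode("ascii")


def _extract_matrix(
    mat: np.ndarray,
    anchor5: str,
    anchor3: str,
    barcode_length: int,
    budget: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized extraction over an (n, read_len) ASCII matrix.

    Returns (candidates (n, barcode_length) uint8, ok mask). Candidate rows
    with ok=False are undefined.
    """
    n, read_len = mat.shape
    a5 = _to_bytes(anchor5)
    a3 = _to_bytes(anchor3)
    amplicon = len(a5) + barcode_length + len(a3)
    n_offsets = read_len - amplicon + 1
    if n_offsets <= 0:
        return np.zeros((n, barcode_length), dtype=np.uint8), np.zeros(n, dtype=bool)
    # scan offsets left to right, keeping only still-unmatched reads in play;
    # the vast majority match at the first offset, so later offsets are cheap
    first = np.zeros(n, dtype=np.int64)
    ok = np.zeros(n, dtype=bool)
    pending = np.arange(n)
    for o in range(n_offsets):
        sub = mat[pending]
        mm5 = (sub[:, o : o + len(a5)] != a5).sum(axis=1)
        mm3 = (
            sub[:, o + len(a5) + barcode_length : o + amplicon] != a3
        ).sum(axis=1)
        hit = (mm5 <= budget) & (mm3 <= budget)
        matched = pending[hit]
        first[matched] = o
        ok[matched] = True
        pending = pending[~hit]
        if pending.size == 0:
            break
    start = first + len(a5)
    cols = start[:, None] + np.arange(barcode_length)[None, :]
    cand = np.take_along_axis(mat, cols, axis=1)
    return cand, ok


# ---------------------------------------------------------------------------
# assignment


def assign_barcode(
    candidate: str, bset: BarcodeSet, max_errors: int | None = None
) -> str:
    """Bounded-distance decode one candidate against the barcode code.

    Returns the label of the unique codeword within Hamming distance
    ``max_errors`` (default: the code's correction radius), ``AMBIGUOUS`` if
    two or more codewords tie at the minimum qualifying distance, or
    ``UNASSIGNED`` if none qualifies. Non-ACGT bases (N) mismatch every
    codeword base.
    """
    if len(candidate) != bset.length:
        raise ValueError(
            f"candidate length {len(candidate)} != barcode length {bset.length}"
        )
    radius = max_errors if max_errors is not None else max_correctable_errors(bset.min_distance)
    cand = _to_bytes(candidate)[None, :]
    code = _decode_matrix(cand, bset.as_matrix(), radius)[0]
    if code == -1:
        return UNASSIGNED
    if code == -2:
        return AMBIGUOUS
    return bset.labels[code]


def _decode_matrix(
    cands: np.ndarray, codewords: np.ndarray, radius: int, chunk: int = 20_000
) -> np.ndarray:
    """Decode (n, L) candidates against (m, L) codewords.

    Returns per-candidate codeword index, −1 for unassigned, −2 for
    ambiguous (≥2 codewords tied at the minimum distance ≤ radius).
    """
    n = cands.shape[0]
    out = np.empty(n, dtype=np.int64)
    for lo in range(0, n, chunk):
        block = cands[lo : lo + chunk]
        d = (block[:, None, :] != codewords[None, :, :]).sum(axis=2)
        dmin = d.min(axis=1)
        nearest = d.argmin(axis=1)
        ties = (d == dmin[:, None]).sum(axis=1)
        res = nearest.copy()
        res[ties > 1] = -2
        res[dmin > radius] = -1
        out[lo : lo + chunk] = res
    return out


# ---------------------------------------------------------------------------
# counting


def count_barcodes(
    fastq_paths: dict[tuple[str, str], str | Path],
    library: "LibraryDesign",
    decode_params: DecodeParams | None = None,
) -> ScreenCounts:
    """Demultiplex every FASTQ in the manifest into a ScreenCounts table.

    ``fastq_paths`` maps (lineage, fraction) to a FASTQ file. Each read is
    routed to exactly one of {barcode, unassigned, ambiguous}; the
    conservation invariant is asserted before returning. A malformed FASTQ
    aborts that file with a diagnostic naming the offending record index.
    """
    params = decode_params or DecodeParams()
    bset = library.assigned_barcode_set()
    radius = (
        params.max_errors
        if params.max_errors is not None
        else max_correctable_errors(bset.min_distance)
    )
    counts: dict[tuple[str, str], dict[str, int]] = {}
    unassigned: dict[tuple[str, str], int] = {}
    ambiguous: dict[tuple[str, str], int] = {}
    totals: dict[tuple[str, str], int] = {}
    for key, path in fastq_paths.items():
        seqs = _read_fastq_seqs(Path(path))
        per_bc, n_un, n_amb = _count_seqs(seqs, library, bset, radius, params)
        counts[key] = per_bc
        unassigned[key] = n_un
        ambiguous[key] = n_amb
        totals[key] = len(seqs)
        rate = (len(seqs) - n_un - n_amb) / len(seqs) if seqs else float("nan")
        logger.info(
            "counted %s/%s: %d reads, assignment rate %.4f, %d unassigned, %d ambiguous",
            key[0], key[1], len(seqs), rate, n_un, n_amb,
        )
    sc = ScreenCounts(
        counts=counts, unassigned=unassigned, ambiguous=ambiguous, total_reads=totals
    )
    sc.check_conservation()
    return sc


def _read_fastq_seqs(path: Path) -> list[str]:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    seqs: list[str] = []
    try:
        with opener(path, "rt") as fh:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                seqs.append(seq.upper())
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ in {path} at record index {len(seqs)}: {exc}"
        ) from exc
    return seqs


def _count_seqs(
    seqs: list[str],
    library: "LibraryDesign",
    bset: BarcodeSet,
    radius: int,
    params: DecodeParams,
) -> tuple[dict[str, int], int, int]:
    per_bc = {b: 0 for b in bset.labels}
    if not seqs:
        return per_bc, 0, 0
    codewords = bset.as_matrix()
    L = bset.length
    n_un = 0
    n_amb = 0
    # group reads by length so each group is a rectangular byte matrix
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    min_len = len(library.anchor5) + L + len(library.anchor3)
    for read_len, group in by_len.items():
        if read_len < min_len:
            n_un += len(group)
            continue
        mat = np.frombuffer("".join(group).encode("ascii"), dtype=np.uint8)
        mat = mat.reshape(len(group), read_len)
        cand, ok = _extract_matrix(
            mat, library.anchor5, library.anchor3, L, params.anchor_mismatch_budget
        )
        if params.revcomp_rescue and (~ok).any():
            rescued = [
                s.translate(_COMPLEMENT)[::-1]
                for s, good in zip(group, ok) if not good
            ]
            rmat = np.frombuffer("".join(rescued).encode("ascii"), dtype=np.uint8)
            rmat = rmat.reshape(len(rescued), read_len)
            rcand, rok = _extract_matrix(
                rmat, library.anchor5, library.anchor3, L, params.anchor_mismatch_budget
            )
            idx = np.flatnonzero(~ok)
            cand[idx[rok]] = rcand[rok]
            ok[idx[rok]] = True
        n_un += int((~ok).sum())
        if ok.any():
            codes = _decode_matrix(cand[ok], codewords, radius)
            n_un += int((codes == -1).sum())
            n_amb += int((codes == -2).sum())
            hit, freq = np.unique(codes[codes >= 0], return_counts=True)
            for h, f in zip(hit, freq):
                per_bc[bset.labels[int(h)]] += int(f)
    return per_bc, n_un, n_amb
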