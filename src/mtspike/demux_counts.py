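"""Barcode demultiplexing and per-well allele counting.

Reads carry a well-specific barcode at their 5' end followed by the
amplicon body; a read may be stored in either orientation, so assignment
tries the read as given and its reverse complement.  Matching is exact
(no mismatch rescue) — synthetic barcodes are generated at pairwise
Hamming distance >= 3, so exact matching is unambiguous.

The per-cell variant allele fraction (heteroplasmy) is the ratio of
variant to total high-quality reads at the single target position:
bases with Phred quality below the cutoff (default 28), bases other than
the two expected alleles, and reads too short to cover the target are
tallied as discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic_data import AmpliconTemplate, reverse_complement

__all__ = [
    "AlleleCount",
    "DemuxResult",
    "load_barcode_table",
    "demultiplex",
    "count_alleles",
    "heteroplasmy",
    "demux_and_count",
]

DEFAULT_MIN_BASE_QUALITY = 28


@dataclass
class AlleleCount:
    """High-quality allele counts at the target position for one well."""

    plate_id: str
    well_id: str
    ref_count: int = 0
    alt_count: int = 0
    n_discarded_low_quality: int = 0

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count


class FastqFormatError(ValueError):
    pass


class BarcodeConfigError(ValueError):
    pass


class UndefinedVAFError(ValueError):
    pass


def _barcode_index(barcodes: pd.DataFrame):
    """Map barcode -> (plate_id, well_id); validates uniqueness and alphabet."""
    if barcodes.empty:
        raise BarcodeConfigError("barcode table is empty")
    idx: dict[str, tuple[str, str]] = {}
    lengths = set()
    for row in barcodes.itertuples(index=False):
        bc = str(row.barcode)
        if set(bc) - set("ACGT"):
            raise BarcodeConfigError(f"barcode {bc!r} has non-ACGT characters")
        if bc in idx:
            raise BarcodeConfigError(f"duplicate barcode {bc!r}")
        idx[bc] = (str(row.plate_id), str(row.well_id))
        lengths.add(len(bc))
    if len(lengths) != 1:
        raise BarcodeConfigError("barcodes must share a single length")
    return idx, lengths.pop()


def load_barcode_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"plate_id", "well_id", "barcode"}
    if not required <= set(df.columns):
        raise BarcodeConfigError(
            f"barcode table must have columns {sorted(required)}")
    return df


def _iter_fastq(fastq):
    """Yield (title, seq, qual) records; fastq is a path or open handle.

    Parser errors surface as :class:`FastqFormatError` carrying the index
    of the offending record.
    """
    def wrapped(handle):
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as e:
                raise FastqFormatError(f"record {i}: {e}") from e
            yield rec
            i += 1

    if hasattr(fastq, "read"):
        yield from wrapped(fastq)
    else:
        with open(fastq) as fh:
            yield from wrapped(fh)


@dataclass
class DemuxResult:
    """Reads per well (oriented to the barcoded strand, barcode stripped)."""

    reads: dict                # (plate_id, well_id) -> list[(seq, qual)]
    n_total: int
    n_unassigned: int

    @property
    def n_assigned(self) -> int:
        return self.n_total - self.n_unassigned


def demultiplex(fastq, barcodes: pd.DataFrame,
                orientation_policy: str = "both") -> DemuxResult:
    """Assign reads to wells by exact 5' barcode match in either orientation.

    A read is assigned iff its prefix matches a barcode as given or, under
    the default ``"both"`` policy, after reverse-complementing the read.
    Assigned reads are stored oriented to the barcoded (template) strand
    with the barcode stripped, so the target offset applies directly.
    Assignment is conservative: each read goes to at most one well and
    assigned + unassigned = total.
    """
    if orientation_policy not in ("both", "forward"):
        raise ValueError("orientation_policy must be 'both' or 'forward'")
    idx, bc_len = _barcode_index(barcodes)
    reads: dict[tuple[str, str], list] = {key: [] for key in idx.values()}
    n_total = n_unassigned = 0
    for rec_no, (title, seq, qual) in enumerate(_iter_fastq(fastq)):
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {rec_no}: sequence/quality length mismatch")
        n_total += 1
        well = idx.get(seq[:bc_len])
        if well is not None:
            reads[well].append((seq[bc_len:], qual[bc_len:]))
            continue
        if orientation_policy == "both":
            rc = reverse_complement(seq)
            well = idx.get(rc[:bc_len])
            if well is not None:
                reads[well].append((rc[bc_len:], qual[::-1][bc_len:]))
                continue
        n_unassigned += 1
    return DemuxResult(reads=reads, n_total=n_total, n_unassigned=n_unassigned)


def count_alleles(read_set, target_offset: int,
                  min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                  template: AmpliconTemplate | None = None,
                  plate_id: str = "", well_id: str = "") -> AlleleCount:
    """Count reference/variant bases at one position with a per-base
    quality cutoff.

    ``read_set`` holds (seq, qual) pairs already oriented to the template
    strand.  A base contributes iff it sits at ``target_offset``, its Phred
    quality (ASCII+33) is >= ``min_base_quality`` and it is one of the two
    expected alleles (default A=reference, G=variant); anything else —
    including reads too short to reach the offset — is discarded.
    """
    ref_base = template.ref_base if template else "A"
    alt_base = template.alt_base if template else "G"
    ref = alt = disc = 0
    for seq, qual in read_set:
        if target_offset >= len(seq):
            disc += 1
            continue
        if ord(qual[target_offset]) - 33 < min_base_quality:
            disc += 1
            continue
        base = seq[target_offset]
        if base == ref_base:
            ref += 1
        elif base == alt_base:
            alt += 1
        else:
            disc += 1
    return AlleleCount(plate_id=plate_id, well_id=well_id, ref_count=ref,
                       alt_count=alt, n_discarded_low_quality=disc)


def heteroplasmy(count: AlleleCount) -> float:
    """VAF = variant / (reference + variant) high-quality reads at the site."""
    depth = count.ref_count + count.alt_count
    if depth < 1:
        raise UndefinedVAFError(
            f"well {count.plate_id}:{count.well_id} has no countable reads; "
            "exclude it upstream")
    return count.alt_count / depth


def demux_and_count(fastq, barcodes: pd.DataFrame, target_offset: int,
                    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
                    template: AmpliconTemplate | None = None,
                    orientation_policy: str = "both") -> pd.DataFrame:
    """Streaming demultiplex + count: one pass over the FASTQ, constant
    memory per well.  Returns a per-well table (plate_id, well_id,
    ref_count, alt_count, depth, n_discarded_low_quality, vaf) with NaN VAF
    at zero depth, plus an ``attrs['n_unassigned']`` bookkeeping entry.
    """
    if orientation_policy not in ("both", "forward"):
        raise ValueError("orientation_policy must be 'both' or 'forward'")
    idx, bc_len = _barcode_index(barcodes)
    ref_base = template.ref_base if template else "A"
    alt_base = template.alt_base if template else "G"
    counts = {key: [0, 0, 0] for key in idx.values()}  # ref, alt, discarded
    n_total = n_unassigned = 0
    off = bc_len + target_offset
    minq_char = chr(33 + min_base_quality)
    for rec_no, (title, seq, qual) in enumerate(_iter_fastq(fastq)):
        if len(seq) != len(qual):
            raise FastqFormatError(
                f"record {rec_no}: sequence/quality length mismatch")
        n_total += 1
        well = idx.get(seq[:bc_len])
        b = q = None
        if well is not None:
            if off < len(seq):
                b, q = seq[off], qual[off]
        elif orientation_policy == "both":
            rc = reverse_complement(seq)
            well = idx.get(rc[:bc_len])
            if well is not None and off < len(seq):
                b, q = rc[off], qual[::-1][off]
        if well is None:
            n_unassigned += 1
            continue
        c = counts[well]
        if b is None or q < minq_char:
            c[2] += 1
        elif b == ref_base:
            c[0] += 1
        elif b == alt_base:
            c[1] += 1
        else:
            c[2] += 1
    rows = []
    for (plate, wellid), (r, a, d) in counts.items():
        rows.append({
            "plate_id": plate, "well_id": wellid, "ref_count": r,
            "alt_count": a, "depth": r + a, "n_discarded_low_quality": d,
            "vaf": a / (r + a) if r + a else np.nan,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_unassigned"] = n_unassigned
    out.attrs["n_total"] = n_total
    return out
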