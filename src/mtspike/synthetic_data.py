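"""Synthetic single-cell amplicon cohorts with fully known ground truth.

Emulates the structure of a plate-based single-cell heteroplasmy assay:
cells of one subset (subject x cell type) are sorted into 96-well plates,
one negative-control well per plate, each well carrying a unique barcoded
forward primer.  Per-cell variant allele fractions are drawn from the same
spike-and-slab family the inference model assumes — a truncated-normal
"spike" of near-zero cells with weight pi and a slab over (0,1) — so every
downstream estimate has an exact planted truth.

Defaults are calibrated to the assay this emulates: log-normal read depths
with median 1,146 whose central 99% spans roughly 200–7,000, subsets of
about 91 cells, and one negative-control well per plate.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubsetTruth",
    "SequencingSpec",
    "PlateLayout",
    "AmpliconTemplate",
    "DEFAULT_TEMPLATE",
    "draw_cell_heteroplasmy",
    "simulate_counts",
    "build_plates",
    "emit_fastq",
    "generate_barcodes",
]


@dataclass(frozen=True)
class SubsetTruth:
    """Planted mixture parameters for one subject x cell-type subset.

    pi_true is the spike weight; spike cells draw their VAF from
    N(mu_true, sigma_true^2) truncated to (0,1) — or sit at exactly 0 when
    ``hard_zero`` is set, emulating complete clearance of the variant.
    The slab is uniform on (0,1) by default, or Beta(a,b) via
    ``slab=("beta", a, b)``.
    """

    subject_id: str
    cell_type: str
    n_cells: int = 91
    pi_true: float = 0.5
    mu_true: float = 0.02
    sigma_true: float = 0.05
    slab: tuple = ("uniform",)
    hard_zero: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_true <= 1.0):
            raise ValueError("pi_true must lie in [0,1]")
        if not (0.0 <= self.mu_true <= 0.2):
            raise ValueError("mu_true must lie in [0, 0.2]")
        if self.sigma_true <= 0:
            raise ValueError("sigma_true must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.slab[0] not in ("uniform", "beta"):
            raise ValueError(f"unknown slab family {self.slab[0]!r}")


@dataclass(frozen=True)
class SequencingSpec:
    """Sequencing-layer parameters of the simulator.

    depth_median / depth_log_sd : log-normal read-depth law, truncated below
        at 1.  The defaults (1,146; 0.70) put the central 99% of depths at
        about 190–7,000.
    error_rate : per-base miscall probability.
    doublet_rate : probability a well receives two cells; such wells carry
        the depth-sum and count-sum of two independent cells.
    failed_well_rate : probability a cell well yields only a trickle of
        reads (failed amplification), with depth uniform on
        [1, failed_well_max_depth].
    negative_control_mean_depth : Poisson mean of stray reads in clean
        negative-control wells.
    contaminated_plate_rate : probability a plate's negative control is
        contaminated and shows a cell-like depth.
    base_quality_mean / base_quality_sd : Phred quality law (normal,
        rounded, clipped to [2, 40]).
    reverse_orientation_prob : probability a read is written as the
        reverse complement of the barcoded strand.
    """

    depth_median: float = 1146.0
    depth_log_sd: float = 0.70
    error_rate: float = 0.005
    doublet_rate: float = 0.02
    failed_well_rate: float = 0.0
    failed_well_max_depth: int = 50
    negative_control_mean_depth: float = 2.0
    contaminated_plate_rate: float = 0.05
    base_quality_mean: float = 35.0
    base_quality_sd: float = 3.0
    reverse_orientation_prob: float = 0.5
    barcode_length: int = 10  # >= 10 packs thousands of codes at Hamming >= 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("error_rate", "doublet_rate", "failed_well_rate",
                     "contaminated_plate_rate", "reverse_orientation_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0,1]")
        if self.error_rate > 0.05:
            raise ValueError("error_rate above 0.05 is outside the assay regime")
        if self.depth_median < 1:
            raise ValueError("depth_median must be >= 1")


@dataclass(frozen=True)
class PlateLayout:
    """One 96-well plate: well ids, barcodes and contents.

    ``wells`` maps well_id -> barcode; ``contents`` maps well_id -> cell id
    or the sentinel ``"negative_control"``.  Exactly one control per plate.
    """

    plate_id: str
    wells: dict
    contents: dict

    def __post_init__(self) -> None:
        if len(set(self.wells.values())) != len(self.wells):
            raise ValueError(f"duplicate barcodes on plate {self.plate_id}")
        n_ctrl = sum(1 for v in self.contents.values() if v == "negative_control")
        if n_ctrl != 1:
            raise ValueError(
                f"plate {self.plate_id} has {n_ctrl} negative controls, expected 1")


WELL_IDS = [f"{r}{c}" for r in string.ascii_uppercase[:8] for c in range(1, 13)]
CONTROL_WELL = "H12"


@dataclass(frozen=True)
class AmpliconTemplate:
    """Amplicon reference with a marked biallelic target position.

    ``target_offset`` is 0-based within the template; the reference base
    there must equal ``ref_base``.  The genomic coordinate of the real
    locus (m.3243, 1-based) is metadata and plays no part in counting.
    """

    seq: str
    target_offset: int
    ref_base: str = "A"
    alt_base: str = "G"

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.seq)):
            raise ValueError("target_offset outside template")
        if self.seq[self.target_offset] != self.ref_base:
            raise ValueError(
                f"template lacks target marker: base at offset "
                f"{self.target_offset} is {self.seq[self.target_offset]!r}, "
                f"expected {self.ref_base!r}")


def _default_template(length: int = 100, offset: int = 50) -> AmpliconTemplate:
    rng = np.random.default_rng(3243)
    bases = rng.choice(list("ACGT"), size=length)
    bases[offset] = "A"
    return AmpliconTemplate(seq="".join(bases), target_offset=offset)


DEFAULT_TEMPLATE = _default_template()

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Heteroplasmy and read-count draws
# ---------------------------------------------------------------------------

def draw_cell_heteroplasmy(truth: SubsetTruth, rng: np.random.Generator,
                           size: int | None = None):
    """Draw per-cell VAF(s) from the planted spike-and-slab mixture.

    With probability ``pi_true`` a cell is a spike cell (truncated-normal
    near-zero VAF, or exactly 0 for a hard-zero spike); otherwise its VAF
    comes from the slab.
    """
    n = 1 if size is None else int(size)
    is_spike = rng.random(n) < truth.pi_true
    out = np.empty(n)
    n_sp = int(is_spike.sum())
    if n_sp:
        if truth.hard_zero:
            out[is_spike] = 0.0
        else:
            a = (0.0 - truth.mu_true) / truth.sigma_true
            b = (1.0 - truth.mu_true) / truth.sigma_true
            u = rng.random(n_sp)
            out[is_spike] = stats.truncnorm.ppf(
                u, a, b, loc=truth.mu_true, scale=truth.sigma_true)
    n_sl = n - n_sp
    if n_sl:
        if truth.slab[0] == "uniform":
            out[~is_spike] = rng.random(n_sl)
        else:
            _, a, b = truth.slab
            out[~is_spike] = rng.beta(a, b, size=n_sl)
    return float(out[0]) if size is None else out


def _draw_depth(spec: SequencingSpec, rng: np.random.Generator) -> int:
    d = rng.lognormal(mean=np.log(spec.depth_median), sigma=spec.depth_log_sd)
    return max(1, int(round(d)))


def simulate_counts(h: float, spec: SequencingSpec, rng: np.random.Generator,
                    depth: int | None = None):
    """Simulate (depth, ref_count, alt_count) for one well at true VAF ``h``.

    The variant read fraction is h(1-e) + (1-h)e with per-base error e, so
    miscalls both create and destroy variant reads symmetrically.
    """
    if not (0.0 <= h <= 1.0):
        raise ValueError("h must lie in [0,1]")
    if depth is None:
        depth = _draw_depth(spec, rng)
    e = spec.error_rate
    p_alt = h * (1.0 - e) + (1.0 - h) * e
    alt = int(rng.binomial(depth, p_alt))
    return depth, depth - alt, alt


# ---------------------------------------------------------------------------
# Barcodes and plates
# ---------------------------------------------------------------------------

def generate_barcodes(n: int, length: int, rng: np.random.Generator,
                      min_hamming: int = 3, max_tries: int = 200_000):
    """Random DNA barcodes with pairwise Hamming distance >= ``min_hamming``.

    Greedy rejection sampling; with length 8 and a few hundred barcodes the
    acceptance rate is high.  Guaranteed separable under exact matching.
    """
    codes: list[str] = []
    arrs = np.empty((n, length), dtype=np.int8)
    k = 0
    tries = 0
    while k < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} "
                f"at Hamming distance >= {min_hamming}")
        cand = rng.integers(0, 4, size=length).astype(np.int8)
        if k == 0 or int((arrs[:k] != cand).sum(axis=1).min()) >= min_hamming:
            arrs[k] = cand
            codes.append("".join("ACGT"[b] for b in cand))
            k += 1
    return codes


def build_plates(cohort, spec: SequencingSpec, rng: np.random.Generator):
    """Lay a cohort of subsets onto 96-well plates and plant read counts.

    Each plate holds cells of a single subset (as in a single-sort-gate
    plate) plus one negative-control well.  Returns ``(plates, truth)``
    where ``truth`` is a per-well DataFrame recording every planted value:
    VAF(s), doublet / failed-well / contamination flags, depth and allele
    counts.  Deterministic given the generator state.
    """
    plates: list[PlateLayout] = []
    rows = []
    capacity = len(WELL_IDS) - 1

    n_plates_total = sum(-(-t.n_cells // capacity) for t in cohort)
    barcodes = generate_barcodes(96 * n_plates_total, spec.barcode_length, rng)
    bc_iter = iter(barcodes)
    plate_no = 0

    for truth in cohort:
        remaining = truth.n_cells
        cell_no = 0
        while remaining > 0:
            plate_no += 1
            plate_id = f"P{plate_no:03d}"
            n_here = min(remaining, capacity)
            remaining -= n_here
            contaminated = bool(rng.random() < spec.contaminated_plate_rate)
            wells = {}
            contents = {}
            cell_wells = [w for w in WELL_IDS if w != CONTROL_WELL][:n_here]
            for w in WELL_IDS:
                wells[w] = next(bc_iter)
            for w in cell_wells:
                cell_no += 1
                cell_id = f"{truth.subject_id}:{truth.cell_type}:{cell_no:04d}"
                contents[w] = cell_id
                is_doublet = bool(rng.random() < spec.doublet_rate)
                is_failed = (not is_doublet) and bool(
                    rng.random() < spec.failed_well_rate)
                h1 = draw_cell_heteroplasmy(truth, rng)
                if is_doublet:
                    h2 = draw_cell_heteroplasmy(truth, rng)
                    d1, _, a1 = simulate_counts(h1, spec, rng)
                    d2, _, a2 = simulate_counts(h2, spec, rng)
                    depth, alt = d1 + d2, a1 + a2
                else:
                    h2 = np.nan
                    if is_failed:
                        depth = int(rng.integers(1, spec.failed_well_max_depth))
                        depth, _, alt = simulate_counts(h1, spec, rng,
                                                        depth=depth)
                    else:
                        depth, _, alt = simulate_counts(h1, spec, rng)
                rows.append({
                    "plate_id": plate_id, "well_id": w,
                    "barcode": wells[w], "cell_id": cell_id,
                    "subject_id": truth.subject_id,
                    "cell_type": truth.cell_type,
                    "is_negative_control": False,
                    "is_doublet": is_doublet, "is_failed_well": is_failed,
                    "plate_contaminated": contaminated,
                    "h_true": h1, "h_true_2": h2,
                    "depth": depth, "alt_count": alt,
                    "ref_count": depth - alt,
                })
            contents[CONTROL_WELL] = "negative_control"
            if contaminated:
                h_c = float(rng.random())
                depth, _, alt = simulate_counts(h_c, spec, rng)
            else:
                h_c = np.nan
                depth = int(rng.poisson(spec.negative_control_mean_depth))
                alt = int(rng.binomial(depth, 0.5)) if depth else 0
            for w in WELL_IDS:
                if w in contents and contents[w] != "negative_control":
                    continue
                if w != CONTROL_WELL:
                    contents.setdefault(w, "empty")
            rows.append({
                "plate_id": plate_id, "well_id": CONTROL_WELL,
                "barcode": wells[CONTROL_WELL], "cell_id": "negative_control",
                "subject_id": truth.subject_id, "cell_type": truth.cell_type,
                "is_negative_control": True,
                "is_doublet": False, "is_failed_well": False,
                "plate_contaminated": contaminated,
                "h_true": h_c, "h_true_2": np.nan,
                "depth": depth, "alt_count": alt, "ref_count": depth - alt,
            })
            plates.append(PlateLayout(plate_id=plate_id, wells=wells,
                                      contents=contents))
    truth_df = pd.DataFrame(rows)
    return plates, truth_df


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def _quality_string(n: int, spec: SequencingSpec,
                    rng: np.random.Generator) -> str:
    if spec.base_quality_sd == 0:
        return chr(33 + int(np.clip(round(spec.base_quality_mean), 2, 40))) * n
    q = np.rint(rng.normal(spec.base_quality_mean, spec.base_quality_sd,
                           size=n))
    q = (np.clip(q, 2, 40) + 33).astype(np.uint8)
    return q.tobytes().decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def emit_fastq(plates, truth: pd.DataFrame, template: AmpliconTemplate,
               spec: SequencingSpec, rng: np.random.Generator, path):
    """Write single-end reads realising the planted per-well allele counts.

    Each read is the well barcode followed by the amplicon template with
    the reference or variant base at the target offset — ``ref_count``
    reference reads and ``alt_count`` variant reads per well, so with
    ``error_rate == 0`` demultiplexing and counting recover the planted
    counts exactly.  Per-base miscalls (``error_rate``) are then applied
    across the whole read, including barcode and target.  Reads are written
    in reverse-complement orientation with ``reverse_orientation_prob``.
    Phred qualities (+33) follow the base-quality law.  Read ids record
    provenance as plate:well:index:allele.  Returns the number of reads
    written.
    """
    barcode_of = {(p.plate_id, w): bc for p in plates
                  for w, bc in p.wells.items()}
    ref_read = (template.seq[:template.target_offset] + template.ref_base
                + template.seq[template.target_offset + 1:])
    alt_read = (template.seq[:template.target_offset] + template.alt_base
                + template.seq[template.target_offset + 1:])
    n_written = 0
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            bc = barcode_of[(row.plate_id, row.well_id)]
            for allele, count in (("ref", row.ref_count),
                                  ("alt", row.alt_count)):
                body = ref_read if allele == "ref" else alt_read
                for i in range(count):
                    seq = _mutate(bc + body, spec.error_rate, rng)
                    qual = _quality_string(len(seq), spec, rng)
                    if rng.random() < spec.reverse_orientation_prob:
                        seq = reverse_complement(seq)
                        qual = qual[::-1]
                        orient = "rc"
                    else:
                        orient = "fwd"
                    rid = (f"{row.plate_id}:{row.well_id}:{n_written}"
                           f":{allele}:{orient}")
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
                    n_written += 1
    return n_written


def barcode_table(plates) -> pd.DataFrame:
    """Flatten plate layouts into a (plate_id, well_id, barcode) table."""
    rows = [{"plate_id": p.plate_id, "well_id": w, "barcode": bc}
            for p in plates for w, bc in p.wells.items()]
    return pd.DataFrame(rows)
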