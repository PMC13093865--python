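"""Uncorrected pairwise distances and per-species barcode diagnostics.

All statistics are built on the *p*-distance — the fraction of mismatching
sites over the columns where both sequences carry an unambiguous A/C/G/T
(pairwise deletion).  Ambiguity codes and gaps are treated as missing, never
as partial matches.  A pair with fewer than ``min_overlap`` jointly
unambiguous sites gets an undefined (NaN) distance.

Per species the library computes:

* ``max_intra`` / ``median_intra`` — over all intraspecific pairs among
  identified sequences with >= 600 unambiguous bp, for species with at least
  three such sequences;
* ``max_intra_loose`` — the same maximum, additionally admitting "cf."
  determinations and sequences down to 300 bp, for species with more than one
  such sequence;
* ``min_inter`` / ``median_min_inter`` — minimum distance to any congeneric
  heterospecific sequence, and the median over the focal species' sequences
  of each sequence's own minimum (monotypic genus groups are not analysed);
* the *barcode gap* verdict (``max_intra`` strictly below ``min_inter``) and
  the *barcode sharing* verdict (``min_inter`` exactly zero, i.e. an
  identical haplotype occurs in two species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    AlignedSeq,
    GenusAlignment,
    SpecimenRecord,
    ValidationError,
    round_half_away,
)

__all__ = [
    "DistanceMatrix",
    "SpeciesDistanceSummary",
    "p_distance",
    "distance_matrix",
    "intraspecific_summary",
    "loose_max_intra",
    "interspecific_summary",
    "barcode_gap",
    "barcode_sharing",
    "species_summaries",
    "summarize_library",
    "percent",
]

MIN_OVERLAP_DEFAULT = 100

_CODE = {c: i for i, c in enumerate("ACGT")}


def _encode(seqs: Sequence[AlignedSeq]) -> tuple[np.ndarray, np.ndarray]:
    """uint8 base codes (255 = missing) and boolean unambiguous mask."""
    n = len(seqs)
    length = len(seqs[0]) if n else 0
    codes = np.full((n, length), 255, dtype=np.uint8)
    for i, s in enumerate(seqs):
        row = np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8)
        for base, value in _CODE.items():
            codes[i][row == ord(base)] = value
    return codes, codes != 255


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix with per-pair overlap counts."""

    ids: list[str]
    values: np.ndarray  # float, NaN where overlap < min_overlap
    overlap: np.ndarray  # int shared-site counts
    min_overlap: int = MIN_OVERLAP_DEFAULT

    def index_of(self, specimen_id: str) -> int:
        return self.ids.index(specimen_id)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])


def p_distance(
    a: AlignedSeq, b: AlignedSeq, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> tuple[float | None, int]:
    """Uncorrected distance between two aligned sequences, pairwise deletion.

    Returns ``(distance, overlap)``; the distance is None when fewer than
    ``min_overlap`` columns are jointly unambiguous.
    """
    if len(a) != len(b):
        raise ValidationError(
            f"unequal column counts: {a.specimen_id} ({len(a)}) vs {b.specimen_id} ({len(b)})"
        )
    both = 0
    diff = 0
    for x, y in zip(a.residues, b.residues):
        if x in _CODE and y in _CODE:
            both += 1
            if x != y:
                diff += 1
    if both < min_overlap:
        return None, both
    return diff / both, both


def distance_matrix(
    aln: GenusAlignment, min_overlap: int = MIN_OVERLAP_DEFAULT
) -> DistanceMatrix:
    """All-pairs p-distances for one genus alignment (vectorised)."""
    seqs = aln.sequences
    if len(seqs) < 2:
        raise ValidationError("distance matrix requires at least two sequences")
    codes, valid = _encode(seqs)
    n = len(seqs)
    values = np.zeros((n, n), dtype=float)
    overlap = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        joint = valid[i] & valid[i + 1 :]
        ov = joint.sum(axis=1)
        mism = ((codes[i] != codes[i + 1 :]) & joint).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(ov > 0, mism / np.maximum(ov, 1), np.nan)
        d = np.where(ov < min_overlap, np.nan, d)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        overlap[i, i + 1 :] = ov
        overlap[i + 1 :, i] = ov
    np.fill_diagonal(values, 0.0)
    np.fill_diagonal(overlap, [s.effective_length for s in seqs])
    return DistanceMatrix([s.specimen_id for s in seqs], values, overlap, min_overlap)


# ---------------------------------------------------------------------------
# per-species statistics

def _pair_values(matrix: DistanceMatrix, ids: Sequence[str]) -> np.ndarray:
    idx = [matrix.index_of(i) for i in ids]
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    return vals[~np.isnan(vals)]


def _eligible_ids(
    records: Mapping[str, SpecimenRecord],
    seqs: Sequence[AlignedSeq],
    species: str,
    det_allowed: set[str],
    min_len: int,
) -> list[str]:
    out = []
    for s in seqs:
        rec = records.get(s.specimen_id)
        if (
            rec is not None
            and rec.species == species
            and rec.det_status in det_allowed
            and s.effective_length >= min_len
        ):
            out.append(s.specimen_id)
    return out


def intraspecific_summary(
    species: str,
    matrix: DistanceMatrix,
    records: Sequence[SpecimenRecord],
    aln: GenusAlignment,
) -> tuple[float | None, float | None]:
    """(max, median) intraspecific p-distance under the strict rule.

    Strict rule: identified determinations, >= 600 unambiguous bp, at least
    three such sequences.  Ineligible species yield ``(None, None)``.
    """
    rec_by_id = {r.specimen_id: r for r in records}
    ids = _eligible_ids(rec_by_id, aln.sequences, species, {"identified"}, 600)
    if len(ids) < 3:
        return None, None
    vals = _pair_values(matrix, ids)
    if vals.size == 0:
        return None, None
    return float(vals.max()), float(np.median(vals))


def loose_max_intra(
    species: str,
    matrix: DistanceMatrix,
    records: Sequence[SpecimenRecord],
    aln: GenusAlignment,
) -> float | None:
    """Maximum intraspecific distance admitting cf. sequences and >= 300 bp."""
    rec_by_id = {r.specimen_id: r for r in records}
    ids = _eligible_ids(rec_by_id, aln.sequences, species, {"identified", "cf"}, 300)
    if len(ids) < 2:
        return None
    vals = _pair_values(matrix, ids)
    if vals.size == 0:
        return None
    return float(vals.max())


def interspecific_summary(
    species: str,
    matrix: DistanceMatrix,
    records: Sequence[SpecimenRecord],
    aln: GenusAlignment,
) -> tuple[float | None, float | None, list[str]]:
    """(min_inter, median_min_inter, nearest neighbours) for one species.

    Comparisons run against identified congeneric sequences (>= 600 bp) of
    other species in the same genus group; monotypic genus groups return the
    null triple.  Nearest neighbours are every species attaining the minimum,
    lexicographically sorted.
    """
    rec_by_id = {r.specimen_id: r for r in records}
    focal = _eligible_ids(rec_by_id, aln.sequences, species, {"identified"}, 600)
    if not focal:
        return None, None, []
    others: dict[str, list[str]] = {}
    for s in aln.sequences:
        rec = rec_by_id.get(s.specimen_id)
        if (
            rec is not None
            and rec.species not in (None, species)
            and rec.det_status == "identified"
            and s.effective_length >= 600
        ):
            others.setdefault(rec.species, []).append(s.specimen_id)
    if not others:
        return None, None, []

    other_ids = [i for ids in others.values() for i in ids]
    other_species = [sp for sp, ids in others.items() for _ in ids]
    fi = [matrix.index_of(i) for i in focal]
    oi = [matrix.index_of(i) for i in other_ids]
    block = matrix.values[np.ix_(fi, oi)]

    per_seq_min = []
    for row in block:
        defined = row[~np.isnan(row)]
        if defined.size:
            per_seq_min.append(float(defined.min()))
    if not per_seq_min:
        return None, None, []
    min_inter = min(per_seq_min)
    median_min = float(np.median(per_seq_min))

    flat = block.ravel()
    sp_all = np.tile(np.array(other_species), len(fi))
    with np.errstate(invalid="ignore"):
        hits = ~np.isnan(flat) & (flat == min_inter)
    neighbours = sorted(set(sp_all[hits].tolist()))
    return min_inter, median_min, neighbours


def barcode_gap(max_intra: float | None, min_inter: float | None) -> bool | None:
    """True when the maximum intraspecific distance is strictly below the
    minimum interspecific one; undefined when either side is."""
    if max_intra is None or min_inter is None:
        return None
    return max_intra < min_inter


def barcode_sharing(min_inter: float | None) -> bool | None:
    """True when an identical haplotype occurs in another species."""
    if min_inter is None:
        return None
    return min_inter == 0.0


@dataclass
class SpeciesDistanceSummary:
    species: str
    n_strict: int
    n_loose: int
    max_intra: float | None
    median_intra: float | None
    max_intra_loose: float | None
    min_inter: float | None
    median_min_inter: float | None
    gap: bool | None
    sharing: bool | None
    nearest_neighbour: str | None
    nearest_neighbours: list[str]


def species_summaries(
    aln: GenusAlignment,
    records: Sequence[SpecimenRecord],
    matrix: DistanceMatrix | None = None,
    extended_area_only: bool = True,
) -> list[SpeciesDistanceSummary]:
    """Full per-species distance summary table for one genus group."""
    if extended_area_only:
        keep = {r.specimen_id for r in records if r.in_extended_area}
        aln = aln.subset(keep)
    if matrix is None:
        matrix = distance_matrix(aln)
    rec_by_id = {r.specimen_id: r for r in records}
    species_list = sorted(
        {
            rec_by_id[s.specimen_id].species
            for s in aln.sequences
            if s.specimen_id in rec_by_id
            and rec_by_id[s.specimen_id].species is not None
            and rec_by_id[s.specimen_id].det_status in ("identified", "cf")
        }
    )
    out = []
    for sp in species_list:
        n_strict = len(_eligible_ids(rec_by_id, aln.sequences, sp, {"identified"}, 600))
        n_loose = len(
            _eligible_ids(rec_by_id, aln.sequences, sp, {"identified", "cf"}, 300)
        )
        max_i, med_i = intraspecific_summary(sp, matrix, records, aln)
        loose = loose_max_intra(sp, matrix, records, aln)
        min_e, med_e, nn = interspecific_summary(sp, matrix, records, aln)
        out.append(
            SpeciesDistanceSummary(
                species=sp,
                n_strict=n_strict,
                n_loose=n_loose,
                max_intra=max_i,
                median_intra=med_i,
                max_intra_loose=loose,
                min_inter=min_e,
                median_min_inter=med_e,
                gap=barcode_gap(max_i, min_e),
                sharing=barcode_sharing(min_e),
                nearest_neighbour=nn[0] if nn else None,
                nearest_neighbours=nn,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[SpeciesDistanceSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(s.__dict__)
        row["nearest_neighbours"] = ";".join(s.nearest_neighbours)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# library-level reporting

def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage rounded half away from zero (one decimal by default)."""
    if denominator == 0:
        return 0.0
    return round_half_away(100.0 * numerator / denominator, ndigits)


def summarize_library(
    summaries: Sequence[SpeciesDistanceSummary],
    records: Sequence[SpecimenRecord],
    monophyly_results: Sequence | None = None,
) -> dict[str, float | int]:
    """Counts and one-decimal percentages for the whole reference library."""
    species = {r.species for r in records if r.species and r.det_status == "identified"}
    n_sequences = len(records)
    n_species = len(species)
    n_de_novo = sum(1 for r in records if r.source == "de_novo")

    by_species: dict[str, int] = {}
    for r in records:
        if r.species and r.det_status == "identified":
            by_species[r.species] = by_species.get(r.species, 0) + 1
    n_singleton = sum(1 for n in by_species.values() if n == 1)

    gap_eligible = [s for s in summaries if s.gap is not None]
    sharing_eligible = [s for s in summaries if s.sharing is not None]
    report: dict[str, float | int] = {
        "n_sequences": n_sequences,
        "n_species": n_species,
        "mean_seqs_per_species": (
            round_half_away(n_sequences / n_species, 1) if n_species else 0.0
        ),
        "n_de_novo": n_de_novo,
        "pct_de_novo": percent(n_de_novo, n_sequences),
        "n_singletons": n_singleton,
        "pct_singletons": percent(n_singleton, n_species),
        "n_gap_eligible": len(gap_eligible),
        "n_gap": sum(1 for s in gap_eligible if s.gap),
        "pct_gap": percent(sum(1 for s in gap_eligible if s.gap), len(gap_eligible)),
        "n_sharing_eligible": len(sharing_eligible),
        "n_sharing": sum(1 for s in sharing_eligible if s.sharing),
        "pct_sharing": percent(
            sum(1 for s in sharing_eligible if s.sharing), len(sharing_eligible)
        ),
    }
    if monophyly_results is not None:
        from .monophyly import summarize_monophyly

        report.update(summarize_monophyly(monophyly_results))
    return report
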