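"""Specimen records, aligned sequences and eligibility filters.

The data model mirrors how continental COI reference libraries are curated:
one metadata row per sequenced specimen (taxonomy, determination status,
WGS84 coordinates at a known precision, provenance and type-material flags)
and one aligned FASTA per genus group.  Genera known to be mutually
non-monophyletic are merged into a single *genus group* before any
between-species comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DET_STATUSES",
    "COORD_PRECISIONS",
    "SOURCES",
    "TYPE_FLAGS",
    "DEFAULT_GENUS_MERGE",
    "SpecimenRecord",
    "AlignedSeq",
    "GenusAlignment",
    "StopCodonResult",
    "ValidationError",
    "genus_group_for",
    "read_metadata",
    "write_metadata",
    "read_alignment",
    "write_alignment",
    "screen_stop_codons",
    "normalize_coordinates",
    "round_half_away",
    "eligibility_filter",
    "ELIGIBILITY_RULES",
]

DET_STATUSES = ("identified", "cf", "group_complex", "genus_only")
COORD_PRECISIONS = ("exact", "toponym_0p1deg", "country_only")
SOURCES = ("de_novo", "genbank", "bold", "sra")
TYPE_FLAGS = frozenset(
    {"type_series", "holotype", "paratype", "neotype", "terra_typica", "type_locality"}
)

# Genus pairs shown to be mutually non-monophyletic are analysed as one unit;
# the map is configuration, these are the defaults.
DEFAULT_GENUS_MERGE: dict[str, str] = {
    "Messor": "Aphaenogaster",
    "Oxyopomyrmex": "Goniomma",
    "Strongylognathus": "Tetramorium",
}

# IUPAC nucleotide one-letter codes, plus alignment gap.
_UNAMBIGUOUS = set("ACGT")
_ALPHABET = set("ACGTRYSWKMBDHVN-")


class ValidationError(ValueError):
    """Raised when an input file or record violates the data contract."""


def genus_group_for(genus: str, merge_map: Mapping[str, str] | None = None) -> str:
    merge_map = DEFAULT_GENUS_MERGE if merge_map is None else merge_map
    return merge_map.get(genus, genus)


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequenced specimen with its curation metadata."""

    specimen_id: str
    genus: str
    species: str | None
    det_status: str = "identified"
    lat: float | None = None
    lon: float | None = None
    coord_precision: str = "exact"
    country: str = ""
    island: str | None = None
    source: str = "de_novo"
    type_flags: frozenset[str] = frozenset()
    faunistic_novelty: bool = False
    in_extended_area: bool = True
    genus_group: str = ""

    def __post_init__(self) -> None:
        if self.det_status not in DET_STATUSES:
            raise ValidationError(
                f"{self.specimen_id}: det_status {self.det_status!r} not in {DET_STATUSES}"
            )
        if self.coord_precision not in COORD_PRECISIONS:
            raise ValidationError(
                f"{self.specimen_id}: coord_precision {self.coord_precision!r} invalid"
            )
        if self.source not in SOURCES:
            raise ValidationError(f"{self.specimen_id}: source {self.source!r} invalid")
        if not TYPE_FLAGS.issuperset(self.type_flags):
            raise ValidationError(
                f"{self.specimen_id}: unknown type flags {set(self.type_flags) - TYPE_FLAGS}"
            )
        if self.coord_precision == "country_only":
            if self.lat is not None or self.lon is not None:
                raise ValidationError(
                    f"{self.specimen_id}: country_only precision forbids coordinates"
                )
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"{self.specimen_id}: latitude {self.lat} out of bounds")
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"{self.specimen_id}: longitude {self.lon} out of bounds")
        if not self.genus_group:
            object.__setattr__(self, "genus_group", genus_group_for(self.genus))


@dataclass(frozen=True)
class AlignedSeq:
    """One aligned barcode; effective length counts unambiguous A/C/G/T."""

    specimen_id: str
    residues: str

    def __post_init__(self) -> None:
        up = self.residues.upper()
        bad = [(i, c) for i, c in enumerate(up) if c not in _ALPHABET]
        if bad:
            i, c = bad[0]
            raise ValidationError(
                f"{self.specimen_id}: illegal character {c!r} at column {i + 1}"
            )
        object.__setattr__(self, "residues", up)

    @property
    def effective_length(self) -> int:
        return sum(1 for c in self.residues if c in _UNAMBIGUOUS)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GenusAlignment:
    """All aligned barcodes of one genus group (equal column counts)."""

    genus_group: str
    sequences: list[AlignedSeq] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = {len(s) for s in self.sequences}
        if len(cols) > 1:
            raise ValidationError(
                f"{self.genus_group}: ragged alignment, column counts {sorted(cols)}"
            )

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def subset(self, ids: Iterable[str]) -> "GenusAlignment":
        keep = set(ids)
        return GenusAlignment(
            self.genus_group, [s for s in self.sequences if s.specimen_id in keep]
        )


# ---------------------------------------------------------------------------
# metadata I/O

_REQUIRED_COLUMNS = [
    "specimen_id",
    "genus",
    "species",
    "det_status",
    "lat",
    "lon",
    "coord_precision",
    "country",
    "island",
    "source",
    "type_flags",
    "faunistic_novelty",
    "in_extended_area",
]


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def read_metadata(
    path: str | Path, merge_map: Mapping[str, str] | None = None
) -> list[SpecimenRecord]:
    """Read the tab-delimited specimen table.

    Missing required columns and duplicated specimen ids are fatal; malformed
    coordinates raise with the offending specimen named rather than being
    dropped silently.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata is missing required column(s): {', '.join(missing)}")
    dupes = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate specimen_id(s): {sorted(set(dupes))}")

    records = []
    for row in df.itertuples(index=False):
        lat = lon = None
        for name, raw in (("lat", row.lat), ("lon", row.lon)):
            if str(raw).strip():
                try:
                    value = float(raw)
                except ValueError:
                    raise ValidationError(
                        f"{row.specimen_id}: malformed {name} value {raw!r}"
                    ) from None
                if name == "lat":
                    lat = value
                else:
                    lon = value
        flags = frozenset(f for f in str(row.type_flags).split(";") if f)
        records.append(
            SpecimenRecord(
                specimen_id=row.specimen_id,
                genus=row.genus,
                species=row.species or None,
                det_status=row.det_status,
                lat=lat,
                lon=lon,
                coord_precision=row.coord_precision,
                country=row.country,
                island=row.island or None,
                source=row.source,
                type_flags=flags,
                faunistic_novelty=_parse_bool(row.faunistic_novelty),
                in_extended_area=_parse_bool(row.in_extended_area),
                genus_group=genus_group_for(row.genus, merge_map),
            )
        )
    return records


def write_metadata(records: Sequence[SpecimenRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "genus": r.genus,
                "species": r.species or "",
                "det_status": r.det_status,
                "lat": "" if r.lat is None else repr(r.lat),
                "lon": "" if r.lon is None else repr(r.lon),
                "coord_precision": r.coord_precision,
                "country": r.country,
                "island": r.island or "",
                "source": r.source,
                "type_flags": ";".join(sorted(r.type_flags)),
                "faunistic_novelty": str(r.faunistic_novelty).lower(),
                "in_extended_area": str(r.in_extended_area).lower(),
            }
        )
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# alignment I/O

def read_alignment(path: str | Path, genus_group: str | None = None) -> GenusAlignment:
    """Read one aligned per-genus FASTA; ragged lengths are fatal."""
    path = Path(path)
    seqs = [
        AlignedSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    name = genus_group if genus_group is not None else path.stem
    return GenusAlignment(name, seqs)


def write_alignment(aln: GenusAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.specimen_id, description="") for s in aln
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# stop-codon screening

@dataclass(frozen=True)
class StopCodonResult:
    status: str  # pass | fail | indeterminate
    best_frame: int | None  # 1-based reading frame, None when indeterminate
    stops_per_frame: tuple[int | None, int | None, int | None] = (None, None, None)


def screen_stop_codons(seq: AlignedSeq | str, code: int = 5) -> StopCodonResult:
    """Screen a barcode for internal stop codons (NUMT / pseudogene signal).

    The gap-stripped sequence is translated in all three forward frames under
    the given genetic code (default: invertebrate mitochondrial, table 5).
    Codons containing ambiguity codes are skipped.  The best frame is the one
    with the fewest stops (ties broken toward the lower frame index); the
    sequence fails only if the best frame still contains a stop.  Sequences
    with fewer than three unambiguous codons in every frame are
    *indeterminate*, not failed.
    """
    residues = (seq.residues if isinstance(seq, AlignedSeq) else seq.upper())
    bases = residues.replace("-", "")
    table = CodonTable.unambiguous_dna_by_id[code]
    stop_codons = set(table.stop_codons)

    stops: list[int] = []
    informative: list[int] = []
    for frame in range(3):
        n_stop = n_codon = 0
        for i in range(frame, len(bases) - 2, 3):
            codon = bases[i : i + 3]
            if set(codon) <= _UNAMBIGUOUS:
                n_codon += 1
                if codon in stop_codons:
                    n_stop += 1
        stops.append(n_stop)
        informative.append(n_codon)

    if max(informative) < 3:
        return StopCodonResult("indeterminate", None)
    best = min(range(3), key=lambda f: (stops[f], f))
    status = "fail" if stops[best] > 0 else "pass"
    return StopCodonResult(status, best + 1, tuple(stops))


# ---------------------------------------------------------------------------
# coordinates

def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for all printed values)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def normalize_coordinates(
    lat: float | None, lon: float | None, precision: str
) -> tuple[float | None, float | None]:
    """Snap toponym-derived coordinates to the 0.1 degree grid.

    Exact coordinates pass through unchanged; country-only records carry no
    coordinates at all.
    """
    if precision not in COORD_PRECISIONS:
        raise ValidationError(f"unknown coordinate precision {precision!r}")
    if precision == "country_only":
        return None, None
    if lat is None or lon is None:
        return lat, lon
    if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
        raise ValidationError(f"coordinates ({lat}, {lon}) outside WGS84 bounds")
    if precision == "exact":
        return lat, lon
    return round_half_away(lat, 1) + 0.0, round_half_away(lon, 1) + 0.0


# ---------------------------------------------------------------------------
# eligibility rules

def _species_eligible_counts(
    records: Mapping[str, SpecimenRecord],
    seqs: Iterable[AlignedSeq],
    det_allowed: set[str],
    min_len: int,
) -> dict[str | None, list[str]]:
    by_species: dict[str | None, list[str]] = {}
    for s in seqs:
        rec = records.get(s.specimen_id)
        if rec is None or rec.species is None:
            continue
        if rec.det_status not in det_allowed:
            continue
        if s.effective_length < min_len:
            continue
        by_species.setdefault(rec.species, []).append(s.specimen_id)
    return by_species


# rule -> (allowed det statuses, min effective length, min sequences/species,
#          genus_group must be non-monotypic)
ELIGIBILITY_RULES: dict[str, tuple[set[str], int, int, bool]] = {
    "strict_intra": ({"identified"}, 600, 3, False),
    "inter": ({"identified"}, 600, 1, True),
    "loose_intra": ({"identified", "cf"}, 300, 2, False),
    "map_display": ({"identified", "cf"}, 0, 1, False),
    "network": ({"identified", "cf"}, 600, 3, False),
}


def eligibility_filter(
    records: Sequence[SpecimenRecord],
    seqs: Iterable[AlignedSeq],
    rule: str,
) -> tuple[list[str], pd.DataFrame]:
    """Apply one of the named per-species eligibility rules.

    Returns the eligible specimen ids plus a per-species verdict table
    (species, n eligible sequences, eligible flag, reason).  Records
    determined only to genus level or as a species group/complex never enter
    per-species statistics.
    """
    if rule not in ELIGIBILITY_RULES:
        raise ValidationError(
            f"unknown eligibility rule {rule!r}; expected one of {sorted(ELIGIBILITY_RULES)}"
        )
    det_allowed, min_len, min_n, needs_congener = ELIGIBILITY_RULES[rule]
    rec_by_id = {r.specimen_id: r for r in records}
    by_species = _species_eligible_counts(rec_by_id, seqs, det_allowed, min_len)

    # monotypy is judged on the species present in the dataset per genus group
    group_species: dict[str, set[str]] = {}
    for r in records:
        if r.species is not None and r.det_status == "identified":
            group_species.setdefault(r.genus_group, set()).add(r.species)
    species_group = {
        r.species: r.genus_group for r in records if r.species is not None
    }

    ids: list[str] = []
    rows = []
    for species in sorted(by_species):
        members = by_species[species]
        n = len(members)
        reason = ""
        ok = n >= min_n
        if not ok:
            reason = f"n={n} < {min_n}"
        elif needs_congener:
            group = species_group.get(species, "")
            if len(group_species.get(group, set())) < 2:
                ok = False
                reason = "monotypic genus group"
        if ok:
            ids.extend(members)
        rows.append({"species": species, "n": n, "eligible": ok, "reason": reason})
    verdicts = pd.DataFrame(rows, columns=["species", "n", "eligible", "reason"])
    return ids, verdicts
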