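"""Synthetic barcode genera with known ground truth.

The generator emits everything the pipeline consumes — an aligned FASTA, a
specimen metadata table and the true specimen tree — for a genus whose
divergences are controlled:

* a pure-birth (Yule) species tree is drawn and its branch lengths rescaled
  so the *smallest* between-species tip-to-tip path equals
  ``target_inter_min``;
* each species hangs a star of specimens off its tip, with per-specimen
  branches uniform on ``[0, target_intra_max / 2]`` so realized maximum
  intraspecific divergence stays at or below ``target_intra_max``;
* sequences evolve site-wise under Jukes–Cantor; any substitution that would
  create a stop codon (invertebrate mitochondrial code) in the defining
  frame is resampled, so every emitted sequence passes quality screening;
* optional introgression copies donor haplotypes into recipient species,
  creating true barcode sharing; optional degradation truncates sequences
  below 600 bp to emulate partial barcodes;
* coordinates come from per-species Gaussian clusters with a configurable
  specimen–cluster association, giving the spatial structure the diversity
  maps are meant to display.

A :class:`TruthTable` reports, per species, the realized maximum
intraspecific and minimum interspecific p-distances computed by a direct
all-pairs comparison on the emitted sequences (independent of the distances
module), whether a haplotype is shared with another species, and the
expected gene-tree status.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import AlignedSeq, GenusAlignment, SpecimenRecord, ValidationError

__all__ = [
    "SimConfig",
    "TruthRow",
    "TruthTable",
    "simulate_genus",
    "inject_introgression",
    "degrade_sequences",
    "realized_stats",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG"}  # invertebrate mitochondrial code


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genus."""

    n_species: int = 6
    seqs_per_species: tuple[int, int] = (3, 12)
    seq_length: int = 658
    target_intra_max: float = 0.02
    target_inter_min: float = 0.08
    introgression_pairs: tuple[tuple[int, int], ...] = ()
    cf_fraction: float = 0.05
    n_spatial_clusters: int = 2
    cluster_association: float = 0.8
    seed: int = 0
    genus: str = "Simulatus"

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValidationError("n_species must be >= 1")
        if self.seqs_per_species[0] < 1 or self.seqs_per_species[0] > self.seqs_per_species[1]:
            raise ValidationError("invalid seqs_per_species range")
        if not self.introgression_pairs:
            if not 0.0 <= self.target_intra_max < self.target_inter_min <= 0.25:
                raise ValidationError(
                    "need 0 <= target_intra_max < target_inter_min <= 0.25 "
                    "when no introgression is configured"
                )
        for donor, recipient in self.introgression_pairs:
            if not (0 <= donor < self.n_species and 0 <= recipient < self.n_species):
                raise ValidationError("introgression pair indexes out of range")
            if donor == recipient:
                raise ValidationError("introgression donor equals recipient")

    def species_name(self, index: int) -> str:
        return f"{self.genus} sp{index + 1:02d}"


@dataclass
class TruthRow:
    species: str
    n_specimens: int
    realized_max_intra: float | None
    realized_min_inter: float | None
    shares_barcode: bool
    expected_tree_status: str  # mono | non_mono_expected | singleton
    review_flag: bool = False


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def row(self, species: str) -> TruthRow:
        for r in self.rows:
            if r.species == species:
                return r
        raise KeyError(species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])


# ---------------------------------------------------------------------------
# tree machinery (internal)

@dataclass
class _Node:
    name: str | None = None
    length: float = 0.0
    children: list["_Node"] = field(default_factory=list)

    def newick(self) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c.newick() for c in self.children)
        label = self.name or ""
        return f"({inner}){label}:{self.length:.6f}"


def _yule_tree(n_tips: int, rng: np.random.Generator) -> _Node:
    """Pure-birth tree; tips named by index, contemporaneous."""
    root = _Node(name="0")
    tips = [root]
    heights = {id(root): 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / len(tips))
        k = int(rng.integers(len(tips)))
        parent = tips[k]
        parent.length = t - heights[id(parent)]
        parent.name = None
        left, right = _Node(), _Node()
        parent.children = [left, right]
        heights[id(left)] = heights[id(right)] = t
        tips[k] = left
        tips.append(right)
    t += rng.exponential(1.0 / len(tips))
    for i, tip in enumerate(tips):
        tip.length = t - heights[id(tip)]
        tip.name = str(i)
    return root


def _jc_branch(p: float) -> float:
    """Expected substitutions per site giving p expected observed differences."""
    return -0.75 * float(np.log(max(1.0 - 4.0 * p / 3.0, 1e-9)))


def _species_tree(
    n_tips: int, target_inter_min: float, rng: np.random.Generator
) -> _Node:
    """Ultrametric species tree with controlled divergence band.

    The topology comes from a pure-birth process; split heights are then
    remapped monotonically so the *shallowest* species pair diverges by
    ``target_inter_min`` (in expected p-distance) and the deepest by at most
    ~0.22, the realistic ceiling for congeneric COI.  Heights are converted
    to substitution units with the inverse Jukes–Cantor transform so the
    expected observed p-distances land on the targets.
    """
    root = _yule_tree(n_tips, rng)

    heights: dict[int, float] = {}

    def measure(node: _Node) -> float:
        if not node.children:
            heights[id(node)] = 0.0
            return 0.0
        h = max(measure(c) + c.length for c in node.children)
        heights[id(node)] = h
        return h

    measure(root)
    internal = [h for h in heights.values() if h > 0.0]
    h_lo_raw, h_hi_raw = min(internal), max(internal)
    half = target_inter_min / 2.0
    h_root = max(half * 1.05, min(0.11, half * 2.75))

    def remap(h: float) -> float:
        if h <= 0.0:
            return 0.0
        if h_hi_raw - h_lo_raw < 1e-12:
            p_half = half
        else:
            p_half = half + (h - h_lo_raw) * (h_root - half) / (h_hi_raw - h_lo_raw)
        return _jc_branch(2.0 * p_half) / 2.0

    def assign(node: _Node, parent_h: float) -> None:
        h = remap(heights[id(node)])
        node.length = max(parent_h - h, 0.0)
        for c in node.children:
            assign(c, h)

    assign(root, remap(heights[id(root)]))
    return root


def _tip_path_lengths(root: _Node) -> dict[tuple[str, str], float]:
    """Tip-to-tip path lengths via recursive merging."""
    out: dict[tuple[str, str], float] = {}

    def walk(node: _Node) -> dict[str, float]:
        if not node.children:
            return {node.name: node.length}
        merged: dict[str, float] = {}
        groups = [walk(c) for c in node.children]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a, da in groups[gi].items():
                    for b, db in groups[gj].items():
                        key = (a, b) if a < b else (b, a)
                        out[key] = da + db
        for g in groups:
            for name, d in g.items():
                merged[name] = d + node.length
        return merged

    walk(root)
    return out


# ---------------------------------------------------------------------------
# sequence evolution

def _random_root_sequence(length: int, rng: np.random.Generator) -> list[str]:
    seq = [_BASES[int(b)] for b in rng.integers(0, 4, size=length)]
    for start in range(0, length - 2, 3):
        while "".join(seq[start : start + 3]) in _STOPS:
            seq[start + 2] = _BASES[int(rng.integers(0, 4))]
    return seq


def _evolve(seq: list[str], branch: float, rng: np.random.Generator) -> list[str]:
    """Jukes–Cantor site-wise evolution with stop-codon avoidance (frame 1)."""
    out = list(seq)
    if branch <= 0:
        return out
    p_mut = 0.75 * (1.0 - np.exp(-4.0 * branch / 3.0))
    hits = np.nonzero(rng.random(len(out)) < p_mut)[0]
    for site in hits:
        current = out[site]
        candidates = [b for b in _BASES if b != current]
        rng.shuffle(candidates)
        codon_start = (site // 3) * 3
        for cand in candidates:
            out[site] = cand
            if codon_start + 3 > len(out):
                break  # trailing partial codon, unconstrained
            if "".join(out[codon_start : codon_start + 3]) not in _STOPS:
                break
            out[site] = current  # would create a stop; try next base
    return out


# ---------------------------------------------------------------------------
# direct oracle on emitted sequences

def _pdist_plain(a: str, b: str) -> float | None:
    both = diff = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            both += 1
            if x != y:
                diff += 1
    return diff / both if both else None


def realized_stats(
    aln: GenusAlignment, records: Sequence[SpecimenRecord]
) -> dict[str, tuple[float | None, float | None, bool]]:
    """Brute-force (max_intra, min_inter, shares) per species.

    Deliberately a plain double loop over emitted sequences, independent of
    the vectorised distances module, so it can serve as an oracle.
    """
    species_of = {r.specimen_id: r.species for r in records}
    seqs = aln.sequences
    stats: dict[str, list] = {}
    for sp in sorted({s for s in species_of.values() if s}):
        stats[sp] = [None, None, False]
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            si, sj = species_of.get(seqs[i].specimen_id), species_of.get(
                seqs[j].specimen_id
            )
            if si is None or sj is None:
                continue
            d = _pdist_plain(seqs[i].residues, seqs[j].residues)
            if d is None:
                continue
            if si == sj:
                if stats[si][0] is None or d > stats[si][0]:
                    stats[si][0] = d
            else:
                for sp in (si, sj):
                    if stats[sp][1] is None or d < stats[sp][1]:
                        stats[sp][1] = d
                if seqs[i].residues == seqs[j].residues:
                    stats[si][2] = True
                    stats[sj][2] = True
    return {sp: tuple(v) for sp, v in stats.items()}


# ---------------------------------------------------------------------------
# public operations

def simulate_genus(
    config: SimConfig,
) -> tuple[GenusAlignment, list[SpecimenRecord], TruthTable, str]:
    """Simulate one genus; returns (alignment, records, truth, true tree)."""
    rng = np.random.default_rng(config.seed)
    n_sp = config.n_species

    # species tree with the shallowest split at the inter-divergence target
    if n_sp > 1:
        sp_tree = _species_tree(n_sp, config.target_inter_min, rng)
    else:
        sp_tree = _Node(name="0", length=0.0)

    # per-species specimen counts and star branch lengths
    lo, hi = config.seqs_per_species
    counts = [int(rng.integers(lo, hi + 1)) for _ in range(n_sp)]

    root_seq = _random_root_sequence(config.seq_length, rng)
    tip_seqs: dict[str, list[str]] = {}

    def descend(node: _Node, seq: list[str]) -> None:
        evolved = _evolve(seq, node.length, rng)
        if not node.children:
            tip_seqs[node.name] = evolved
        else:
            for c in node.children:
                descend(c, evolved)

    descend(sp_tree, root_seq)

    sequences: list[AlignedSeq] = []
    records: list[SpecimenRecord] = []
    specimen_nodes: dict[int, _Node] = {}
    centers = {
        i: np.column_stack(
            [
                rng.uniform(36.0, 60.0, size=config.n_spatial_clusters),
                rng.uniform(-9.0, 30.0, size=config.n_spatial_clusters),
            ]
        )
        for i in range(n_sp)
    }

    for i in range(n_sp):
        species = config.species_name(i)
        anc = tip_seqs[str(i)]
        star = _Node(name=None, length=0.0)
        for k in range(counts[i]):
            sid = f"SIM{i + 1:02d}_{k + 1:02d}"
            branch = float(rng.uniform(0.0, config.target_intra_max / 2.0))
            seq = _evolve(anc, branch, rng)
            star.children.append(_Node(name=sid, length=branch))
            # spatial cluster with lineage association
            if rng.random() < config.cluster_association:
                cluster = k % config.n_spatial_clusters
            else:
                cluster = int(rng.integers(config.n_spatial_clusters))
            lat, lon = centers[i][cluster] + rng.normal(0.0, 0.5, size=2)
            lat = float(np.clip(lat, -89.9, 89.9))
            lon = float(np.clip(lon, -179.9, 179.9))
            det = "cf" if rng.random() < config.cf_fraction else "identified"
            sequences.append(AlignedSeq(sid, "".join(seq)))
            records.append(
                SpecimenRecord(
                    specimen_id=sid,
                    genus=config.genus,
                    species=species,
                    det_status=det,
                    lat=round(lat, 4),
                    lon=round(lon, 4),
                    coord_precision="exact",
                    country="SIM",
                    source="de_novo",
                    in_extended_area=True,
                )
            )
        specimen_nodes[i] = star

    # graft specimen stars onto the species tree tips
    def graft(node: _Node) -> None:
        if not node.children:
            idx = int(node.name)
            node.name = None
            node.children = specimen_nodes[idx].children
        else:
            for c in node.children:
                graft(c)

    graft(sp_tree)
    true_tree = sp_tree.newick().rsplit(":", 1)[0] + ";"

    aln = GenusAlignment(config.genus, sequences)
    for donor, recipient in config.introgression_pairs:
        aln = inject_introgression(
            aln,
            records,
            config.species_name(donor),
            config.species_name(recipient),
            n_specimens=1,
            seed=int(rng.integers(2**31 - 1)),
        )

    truth = build_truth_table(aln, records, config)
    return aln, records, truth, true_tree


def build_truth_table(
    aln: GenusAlignment, records: Sequence[SpecimenRecord], config: SimConfig
) -> TruthTable:
    stats = realized_stats(aln, records)
    recipients = {
        config.species_name(r) for _, r in config.introgression_pairs
    }
    donors = {config.species_name(d) for d, _ in config.introgression_pairs}
    counts: dict[str, int] = {}
    for r in records:
        if r.species:
            counts[r.species] = counts.get(r.species, 0) + 1
    rows = []
    for sp in sorted(stats):
        max_i, min_e, shares = stats[sp]
        n = counts.get(sp, 0)
        if sp in recipients:
            status = "non_mono_expected"
        elif n == 1 and config.n_species > 1:
            status = "singleton"
        else:
            status = "mono"
        rows.append(
            TruthRow(
                species=sp,
                n_specimens=n,
                realized_max_intra=max_i,
                realized_min_inter=min_e,
                shares_barcode=shares or sp in recipients or sp in donors,
                expected_tree_status=status,
                review_flag=sp in recipients and n == 1,
            )
        )
    return TruthTable(rows)


def inject_introgression(
    aln: GenusAlignment,
    records: Sequence[SpecimenRecord],
    donor: str,
    recipient: str,
    n_specimens: int,
    seed: int,
) -> GenusAlignment:
    """Replace recipient sequences with copies of random donor haplotypes."""
    species_of = {r.specimen_id: r.species for r in records}
    donor_seqs = [s for s in aln if species_of.get(s.specimen_id) == donor]
    recip_seqs = [s for s in aln if species_of.get(s.specimen_id) == recipient]
    if not donor_seqs or not recip_seqs:
        raise ValidationError("donor and recipient must both have sequences")
    if n_specimens > len(recip_seqs):
        raise ValidationError(
            f"cannot replace {n_specimens} of {len(recip_seqs)} recipient sequences"
        )
    if n_specimens == 0:
        return aln
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(recip_seqs), size=n_specimens, replace=False)
    replace_ids = {recip_seqs[int(i)].specimen_id for i in chosen}
    new_seqs = []
    for s in aln:
        if s.specimen_id in replace_ids:
            src = donor_seqs[int(rng.integers(len(donor_seqs)))]
            new_seqs.append(AlignedSeq(s.specimen_id, src.residues))
        else:
            new_seqs.append(s)
    return GenusAlignment(aln.genus_group, new_seqs)


def degrade_sequences(
    aln: GenusAlignment,
    fraction_short: float,
    min_len: int,
    seed: int,
) -> GenusAlignment:
    """Mask sequence tails with N so a fraction fall below 600 effective bp."""
    if not 0.0 <= fraction_short <= 1.0:
        raise ValidationError("fraction_short must be in [0, 1]")
    if min_len < 300:
        raise ValidationError("min_len below the 300 bp library floor")
    if fraction_short == 0.0:
        return aln
    rng = np.random.default_rng(seed)
    n = len(aln)
    n_short = int(round(fraction_short * n))
    chosen = set(rng.choice(n, size=n_short, replace=False).tolist())
    new_seqs = []
    for idx, s in enumerate(aln):
        if idx not in chosen or s.effective_length <= min_len:
            new_seqs.append(s)
            continue
        target = int(rng.integers(min_len, min(600, s.effective_length + 1)))
        chars = list(s.residues)
        eff = s.effective_length
        for pos in range(len(chars) - 1, -1, -1):
            if eff <= target:
                break
            if chars[pos] in _BASES:
                chars[pos] = "N"
                eff -= 1
        new_seqs.append(AlignedSeq(s.specimen_id, "".join(chars)))
    return GenusAlignment(aln.genus_group, new_seqs)
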