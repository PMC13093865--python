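"""PCoA colour assignment, grid aggregation and map products."""

from __future__ import annotations

import numpy as np
import pytest

from antatlas.atlas import (
    GREY,
    assign_colours,
    caption_stats,
    colour_at,
    grid_assign,
    pcoa_2d,
    render_maps,
    unit_square_scale,
)
from antatlas.distances import (
    SpeciesDistanceSummary,
    distance_matrix,
    species_summaries,
)
from antatlas.haplonet import collapse_haplotypes
from antatlas.records import AlignedSeq, GenusAlignment, ValidationError
from conftest import make_record, seq_with_snps

L = 658


def embedded_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


class TestPCoA:
    def test_two_haplotypes_opposite_ends(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        scaled = unit_square_scale(pcoa_2d(d, ["h1", "h2"]))
        assert scaled[:, 1].tolist() == [0.5, 0.5]
        assert sorted(scaled[:, 0].tolist()) == [0.0, 1.0]

    def test_three_equidistant_embed_exactly(self):
        d = np.full((3, 3), 0.06)
        np.fill_diagonal(d, 0.0)
        coords = pcoa_2d(d, ["h1", "h2", "h3"])
        emb = embedded_distances(coords)
        assert np.allclose(emb[~np.eye(3, dtype=bool)], 0.06, atol=1e-9)

    def test_rank_two_euclidean_reproduced(self):
        # four points on a rectangle: exactly rank-2 Euclidean
        pts = np.array([[0, 0], [0.1, 0], [0, 0.04], [0.1, 0.04]])
        d = embedded_distances(pts)
        coords = pcoa_2d(d, [f"h{i}" for i in range(4)])
        assert np.allclose(embedded_distances(coords), d, atol=1e-9)

    def test_zero_distance_pair_identical_positions(self):
        d = np.array(
            [[0.0, 0.0, 0.05], [0.0, 0.0, 0.05], [0.05, 0.05, 0.0]]
        )
        coords = pcoa_2d(d, ["h1", "h2", "h3"])
        assert np.allclose(coords[0], coords[1], atol=1e-12)

    def test_all_null_error(self):
        with pytest.raises(ValidationError):
            pcoa_2d(np.full((2, 2), np.nan), ["a", "b"])

    def test_matches_independent_pcoa_implementation(self):
        # cross-check the double-centering/eigendecomposition route against
        # scikit-bio's ordination on a full-rank 4-point configuration
        import skbio

        pts = np.array([[0.0, 0.0], [0.09, 0.01], [0.02, 0.07], [0.11, 0.08]])
        d = embedded_distances(pts)
        ids = [f"h{i}" for i in range(4)]
        ours = pcoa_2d(d, ids)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d, ids), number_of_dimensions=2
        ).samples.to_numpy()
        # axes agree up to sign
        for axis in range(2):
            col = ref[:, axis]
            assert np.allclose(col, ours[:, axis], atol=1e-9) or np.allclose(
                -col, ours[:, axis], atol=1e-9
            )

    def test_sign_convention_is_order_invariant(self):
        d = np.array(
            [[0.0, 0.02, 0.08], [0.02, 0.0, 0.07], [0.08, 0.07, 0.0]]
        )
        ids = ["h1", "h2", "h3"]
        c1 = pcoa_2d(d, ids)
        perm = [2, 0, 1]
        c2 = pcoa_2d(d[np.ix_(perm, perm)], [ids[i] for i in perm])
        for k, i in enumerate(perm):
            assert np.allclose(c2[k], c1[i], atol=1e-9)


class TestUnitSquare:
    def test_min_max_scaling(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        out = unit_square_scale(pos)
        assert out[:, 0].tolist() == [0.0, 1.0 / 3.0, 1.0]

    def test_degenerate_axis_half(self):
        pos = np.array([[2.0, 5.0], [3.0, 5.0]])
        out = unit_square_scale(pos)
        assert out[:, 1].tolist() == [0.5, 0.5]

    def test_idempotent(self):
        pos = np.array([[0.0, 0.2], [0.4, 1.0], [1.0, 0.0]])
        once = unit_square_scale(pos)
        assert np.allclose(unit_square_scale(once), once)


class TestColourAt:
    @pytest.mark.parametrize(
        "uv,rgb",
        [
            ((0, 0), (0, 0, 255)),
            ((1, 0), (255, 255, 0)),
            ((0, 1), (0, 255, 0)),
            ((1, 1), (255, 0, 0)),
        ],
    )
    def test_corners(self, uv, rgb):
        assert colour_at(*uv) == rgb

    def test_centre_is_componentwise_corner_mean(self):
        corners = [(0, 0, 255), (255, 255, 0), (0, 255, 0), (255, 0, 0)]
        mean = tuple(
            int(np.floor(sum(c[k] for c in corners) / 4 + 0.5)) for k in range(3)
        )
        assert colour_at(0.5, 0.5) == mean == (128, 128, 64)

    def test_out_of_square_error(self):
        with pytest.raises(ValidationError):
            colour_at(1.2, 0.0)


class TestAssignColours:
    def _haps(self, strings):
        seqs = [AlignedSeq(f"x{i + 1}", s) for i, s in enumerate(strings)]
        haps = collapse_haplotypes(seqs)
        reps = [AlignedSeq(h.hap_id, h.representative.residues) for h in haps.haplotypes]
        matrix = distance_matrix(GenusAlignment("sp", reps)) if len(reps) > 1 else None
        return seqs, haps, matrix

    def test_two_sequences_grey(self):
        seqs, haps, matrix = self._haps(["A" * L, "T" + "A" * (L - 1)])
        out = assign_colours("sp", haps, matrix, n_sequences=2)
        assert out.grey_flag
        assert all(c == GREY for c in out.colours.values())

    def test_no_variation_grey(self):
        seqs, haps, matrix = self._haps(["A" * L] * 5)
        out = assign_colours("sp", haps, matrix, n_sequences=5)
        assert out.grey_flag

    def test_divergent_clades_get_clustered_colours(self):
        strings = [
            "A" * L,
            "A" * L,
            seq_with_snps(L, {0: "T"}),
            seq_with_snps(L, {i: "C" for i in range(40)}),
            seq_with_snps(L, {i: "C" for i in range(40)} | {50: "G"}),
        ]
        seqs, haps, matrix = self._haps(strings)
        out = assign_colours("sp", haps, matrix, n_sequences=5)
        assert not out.grey_flag
        member = haps.member_map()
        c = {sid: np.array(out.colours[member[sid]], dtype=float) for sid in member}
        within_a = np.linalg.norm(c["x1"] - c["x3"])
        within_b = np.linalg.norm(c["x4"] - c["x5"])
        between = np.linalg.norm(c["x1"] - c["x4"])
        assert within_a < between and within_b < between

    def test_identical_haplotypes_share_colour(self):
        strings = ["A" * L, "A" * L, seq_with_snps(L, {0: "T"}), seq_with_snps(L, {1: "G"})]
        seqs, haps, matrix = self._haps(strings)
        out = assign_colours("sp", haps, matrix, n_sequences=4)
        member = haps.member_map()
        assert member["x1"] == member["x2"]
        assert out.colour_of(member["x1"]) == out.colour_of(member["x2"])

    def test_grey_rule_holds_across_synthetic_species(self, sim_genus):
        aln, records, _, _ = sim_genus
        by_species: dict[str, list] = {}
        for r in records:
            if r.species and r.det_status in ("identified", "cf"):
                by_species.setdefault(r.species, []).append(r.specimen_id)
        for sp, ids in by_species.items():
            seqs = [s for s in aln if s.specimen_id in set(ids) and s.effective_length >= 600]
            haps = collapse_haplotypes(seqs)
            reps = [AlignedSeq(h.hap_id, h.representative.residues) for h in haps.haplotypes]
            matrix = (
                distance_matrix(GenusAlignment(sp, reps)) if len(reps) > 1 else None
            )
            out = assign_colours(sp, haps, matrix, n_sequences=len(seqs))
            defined = (
                matrix.values[~np.isnan(matrix.values)] if matrix is not None else np.array([])
            )
            max_intra = float(defined.max()) if defined.size else None
            expect_grey = len(seqs) < 3 or not max_intra
            assert out.grey_flag == expect_grey


class TestGrid:
    def test_single_location_single_cell(self):
        records = [
            make_record(f"x{i}", "sp", lat=40.0, lon=3.0) for i in range(4)
        ]
        colours = {f"x{i}": (0, 0, 255) if i < 3 else (255, 0, 0) for i in range(4)}
        cells = grid_assign(records, colours)
        assert len(cells) == 1
        assert cells[0].sector_fractions == {(0, 0, 255): 0.75, (255, 0, 0): 0.25}

    def test_island_separated_despite_same_coordinates(self):
        records = [
            make_record("x1", "sp", lat=40.0, lon=3.0),
            make_record("x2", "sp", lat=40.0, lon=3.0),
            make_record("x3", "sp", lat=40.0, lon=3.0, island="Menorca"),
        ]
        cells = grid_assign(records, {})
        assert len(cells) == 2
        island = [c for c in cells if c.cell_id.startswith("island:")]
        assert island and island[0].member_ids == ["x3"]

    def test_every_plotted_specimen_in_exactly_one_cell(self, sim_genus):
        _, records, _, _ = sim_genus
        cells = grid_assign(records, {})
        seen = [m for c in cells for m in c.member_ids]
        plotted = [
            r.specimen_id
            for r in records
            if r.lat is not None and r.det_status in ("identified", "cf")
        ]
        assert sorted(seen) == sorted(plotted)

    def test_sector_fractions_sum_to_one(self, sim_genus):
        _, records, _, _ = sim_genus
        for cell in grid_assign(records, {}):
            assert sum(cell.sector_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_finer_grid_spreads_points(self):
        rng = np.random.default_rng(5)
        records = [
            make_record(f"x{i}", "sp", lat=float(35 + 10 * rng.random()),
                        lon=float(0 + 10 * rng.random()))
            for i in range(300)
        ]
        coarse = len(grid_assign(records, {}, cell_target=6))
        fine = len(grid_assign(records, {}, cell_target=24))
        assert fine > coarse

    def test_no_coordinates_empty(self):
        records = [make_record("x1", "sp", coord_precision="country_only")]
        assert grid_assign(records, {}) == []


class TestCaptionAndRender:
    def _summary(self, **kwargs):
        base = dict(
            species="sp", n_strict=4, n_loose=6, max_intra=0.01, median_intra=0.005,
            max_intra_loose=0.02, min_inter=0.05, median_min_inter=0.06,
            gap=True, sharing=False, nearest_neighbour="other",
            nearest_neighbours=["other"],
        )
        base.update(kwargs)
        return SpeciesDistanceSummary(**base)

    def test_caption_copies_distance_outputs(self):
        stats = caption_stats(self._summary())
        assert stats.max_intra_strict == 0.01
        assert stats.max_intra_loose == 0.02
        assert stats.n_loose >= stats.n_strict

    def test_strict_ineligible_renders_na(self):
        stats = caption_stats(self._summary(n_strict=2, max_intra=None, median_intra=None))
        assert stats.n_strict is None
        assert "n/a" in stats.render()

    def test_render_emits_tsv_twins(self, tmp_path, sim_genus):
        aln, records, _, _ = sim_genus
        sp = records[0].species
        sp_records = [r for r in records if r.species == sp]
        cells = grid_assign(sp_records, {})
        out = render_maps(sp, sp_records, {}, cells, tmp_path, write_images=False)
        import pandas as pd

        sectors = pd.read_csv(out["diversity_table"], sep="\t")
        assert sectors.groupby("cell")["fraction"].sum().round(9).eq(1.0).all()
        specimens = pd.read_csv(out["specimen_table"], sep="\t")
        novel = specimens[specimens["faunistic_novelty"]]
        assert (novel["marker"] == "diamond").all()
        assert (specimens[~specimens["faunistic_novelty"]]["marker"] == "circle").all()

    def test_no_coordinates_tables_empty(self, tmp_path):
        records = [make_record("x1", "sp", coord_precision="country_only")]
        out = render_maps("sp", records, {}, [], tmp_path, write_images=True)
        import pandas as pd

        assert pd.read_csv(out["diversity_table"], sep="\t").empty
        assert "image" not in out
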