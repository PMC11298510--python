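"""Sector spans, gaps, ribbon tiling, palettes and label placement."""

import math

import pytest

from tetrachord import (
    DimerClass,
    EmptyTableError,
    GapInfeasibleError,
    LabelMode,
    LayoutConfig,
    NodeClass,
    SectorOrder,
    TermRef,
    compute_layout,
    decompose,
    interpolate_palette,
    layout_from_json,
    layout_to_json,
)
from tetrachord.dimers import Dimer, DimerTable
from tetrachord.fixtures import ozone_toy, make_tetramer_table


def one_dimer_table():
    c = TermRef("ozone", "C1", NodeClass.CHEMICAL)
    g = TermRef("PTGFR", "G1", NodeClass.GENE)
    return DimerTable(
        dimers=[Dimer(DimerClass.CHEMICAL_GENE, c, g, 1)], n_tetramers=1)


def many_sector_table(n_genes):
    """One chemical fanned out to n_genes genes -> n_genes + 1 sectors."""
    c = TermRef("chem", "C1", NodeClass.CHEMICAL)
    dimers = [
        Dimer(DimerClass.CHEMICAL_GENE, c,
              TermRef(f"g{i:04d}", f"G{i:04d}", NodeClass.GENE), 1)
        for i in range(n_genes)
    ]
    return DimerTable(dimers=dimers, n_tetramers=n_genes)


class TestSectorSpans:
    def test_two_node_symmetric_case_gives_179_degree_sectors(self):
        layout = compute_layout(one_dimer_table(), LayoutConfig(gap_degree=1))
        assert len(layout.sectors) == 2
        for s in layout.sectors:
            assert s.span == pytest.approx(179.0, abs=1e-9)
        r = layout.ribbons[0]
        # each ribbon span covers its entire sector
        assert r.source_span == (layout.sectors[0].theta_start,
                                 layout.sectors[0].theta_end)
        assert r.target_span == (layout.sectors[1].theta_start,
                                 layout.sectors[1].theta_end)

    @pytest.mark.parametrize("seed", range(3))
    def test_spans_match_closed_form_and_conserve_angle(self, seed):
        tset = make_tetramer_table(150, cardinalities=(6, 20, 25, 4),
                                   seed=seed)
        table = decompose(tset)
        config = LayoutConfig(gap_degree=0.5)
        layout = compute_layout(table, config)
        n = len(layout.sectors)
        total_w = sum(s.weight for s in layout.sectors)
        for s in layout.sectors:
            expected = (360.0 - n * 0.5) * s.weight / total_w
            assert s.span == pytest.approx(expected, rel=1e-12)
        total = sum(s.span for s in layout.sectors) + n * 0.5
        assert total == pytest.approx(360.0, abs=1e-9)

    def test_span_ratios_proportional_to_weights(self):
        table = decompose(ozone_toy())
        layout = compute_layout(table)
        s = layout.sectors
        for a in s:
            for b in s:
                assert a.span / b.span == pytest.approx(
                    a.weight / b.weight, rel=1e-9)

    def test_clockwise_class_order_and_alphabetical_within_class(self):
        layout = compute_layout(decompose(ozone_toy()))
        classes = [s.node.node_class for s in layout.sectors]
        assert classes == sorted(classes, key=lambda c: c.order)
        for cls in NodeClass:
            labels = [s.label.casefold() for s in layout.sectors
                      if s.node.node_class is cls]
            assert labels == sorted(labels)
        # angles strictly decrease (clockwise) from the start angle
        starts = [s.theta_start for s in layout.sectors]
        assert starts[0] == 90.0
        assert all(a > b for a, b in zip(starts, starts[1:]))

    def test_weight_ordering_option(self):
        tset = make_tetramer_table(80, seed=4)
        layout = compute_layout(
            decompose(tset), LayoutConfig(sector_order=SectorOrder.WEIGHT))
        for cls in NodeClass:
            weights = [s.weight for s in layout.sectors
                       if s.node.node_class is cls]
            assert weights == sorted(weights, reverse=True)


class TestRibbonTiling:
    @pytest.mark.parametrize("seed", range(3))
    def test_ribbons_tile_every_sector_exactly(self, seed):
        tset = make_tetramer_table(120, cardinalities=(5, 15, 20, 3),
                                   seed=seed)
        layout = compute_layout(decompose(tset))
        for sector in layout.sectors:
            spans = []
            for r in layout.ribbons:
                if r.dimer.source.key == sector.node.key:
                    spans.append(r.source_span)
                if r.dimer.target.key == sector.node.key:
                    spans.append(r.target_span)
            spans.sort(key=lambda sp: -sp[0])
            # no gaps, no overlaps, full coverage
            assert spans[0][0] == pytest.approx(sector.theta_start, abs=1e-9)
            assert spans[-1][1] == pytest.approx(sector.theta_end, abs=1e-9)
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 == pytest.approx(b0, abs=1e-9)
            total = sum(a - b for a, b in spans)
            assert total == pytest.approx(sector.span, abs=1e-9)

    def test_ribbon_width_fraction_equals_frequency_fraction(self):
        layout = compute_layout(decompose(ozone_toy()))
        for r in layout.ribbons:
            src = layout.sector_for(r.dimer.source.key)
            width = r.source_span[0] - r.source_span[1]
            assert width / src.span == pytest.approx(
                r.dimer.frequency / src.weight, rel=1e-9)


class TestFeasibility:
    def test_gap_infeasible_at_exact_boundary(self):
        table = many_sector_table(359)  # 360 sectors
        with pytest.raises(GapInfeasibleError) as exc:
            compute_layout(table, LayoutConfig(gap_degree=1.0))
        assert exc.value.largest_feasible_gap == pytest.approx(1.0)

    def test_just_below_boundary_succeeds(self):
        table = many_sector_table(359)
        layout = compute_layout(table, LayoutConfig(gap_degree=0.999))
        assert len(layout.sectors) == 360

    def test_400_sectors_at_gap_1_reports_bound_below_0_9(self):
        table = many_sector_table(399)  # 400 sectors
        with pytest.raises(GapInfeasibleError) as exc:
            compute_layout(table, LayoutConfig(gap_degree=1.0))
        assert exc.value.largest_feasible_gap == pytest.approx(0.9)
        assert "0.9" in str(exc.value)

    def test_empty_table_is_a_distinct_error(self):
        with pytest.raises(EmptyTableError):
            compute_layout(DimerTable())

    def test_warn_limit_is_warning_not_error(self):
        tset = make_tetramer_table(60, seed=2)
        table = decompose(tset)
        layout = compute_layout(table,
                                LayoutConfig(tetramer_warn_limit=10))
        assert any("exceed" in w for w in layout.diagnostics.warnings)


class TestColors:
    def test_single_node_class_gets_first_endpoint(self):
        layout = compute_layout(decompose(ozone_toy()))
        chem = [s for s in layout.sectors
                if s.node.node_class is NodeClass.CHEMICAL]
        assert len(chem) == 1
        assert chem[0].color == "#9ecae1"

    def test_two_node_class_gets_both_endpoints(self):
        assert interpolate_palette(("#000000", "#ffffff"), 2) == \
            ["#000000", "#ffffff"]

    def test_five_node_black_white_gradient_is_even_grays(self):
        grays = interpolate_palette(("black", "white"), 5)
        assert grays == ["#000000", "#404040", "#808080", "#bfbfbf",
                         "#ffffff"]

    def test_ribbon_takes_source_sector_color(self):
        layout = compute_layout(decompose(ozone_toy()))
        by_key = {s.node.key: s.color for s in layout.sectors}
        for r in layout.ribbons:
            assert r.color == by_key[r.dimer.source.key]

    def test_unparsable_color_named_in_error(self):
        with pytest.raises(ValueError, match="not-a-color"):
            interpolate_palette(("not-a-color", "red"), 3)


class TestLabels:
    @pytest.mark.parametrize("scale,expected", [(0.5, 5.0), (1.0, 10.0),
                                                (1.5, 15.0)])
    def test_font_scale_multiplies_base_size(self, scale, expected):
        layout = compute_layout(decompose(ozone_toy()),
                                LayoutConfig(font_scale=scale))
        for s in layout.sectors:
            assert s.anchor.font_size == pytest.approx(expected)

    def test_id_mode_uses_accessions(self):
        layout = compute_layout(decompose(ozone_toy()),
                                LayoutConfig(label_mode=LabelMode.ID))
        labels = {s.anchor.text for s in layout.sectors}
        assert "D000402" in labels and "Airway Obstruction" not in labels

    def test_anchor_sits_at_sector_midpoint_outside_ring(self):
        layout = compute_layout(decompose(ozone_toy()))
        for s in layout.sectors:
            assert s.anchor.angle == pytest.approx(
                0.5 * (s.theta_start + s.theta_end))
            assert s.anchor.radius > 1.0

    def test_rotation_keeps_text_upright(self):
        tset = make_tetramer_table(50, seed=1)
        layout = compute_layout(decompose(tset))
        for s in layout.sectors:
            rot = s.anchor.rotation % 360.0
            assert rot <= 90.0 + 1e-9 or rot > 270.0 - 1e-9


class TestDeterminismAndSerialization:
    def test_identical_inputs_give_identical_layout(self):
        tset = make_tetramer_table(100, seed=12)
        a = layout_to_json(compute_layout(decompose(tset)))
        b = layout_to_json(compute_layout(decompose(tset)))
        assert a == b

    def test_json_round_trip_preserves_geometry(self):
        layout = compute_layout(decompose(ozone_toy()))
        again = layout_from_json(layout_to_json(layout))
        assert layout_to_json(again) == layout_to_json(layout)
        for s1, s2 in zip(layout.sectors, again.sectors):
            assert math.isclose(s1.theta_start, s2.theta_start)
            assert s1.color == s2.color
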