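"""The sliding-window engine: limiting cases, brute-force equivalence, export."""

from __future__ import annotations

import numpy as np
import pytest

from structwin.errors import InputError, ScoringError
from structwin.fixtures import FixtureSpec, make_fixture
from structwin.mapper import (
    ScoringFunction,
    build_residue_map,
    export_results,
    get_function,
    read_json_scores,
    run_window_analysis,
    write_json,
    write_tsv,
)
from structwin.seqalign import NumericTable
from structwin.spatial import NeighborQueryConfig
from structwin.structures import ResidueId

from oracles import oracle_window_scores


@pytest.fixture(scope="module")
def helix10_fixture():
    spec = FixtureSpec(n_residues=10, n_sequences=8, seed=31, mutation_rate=0.5)
    return make_fixture(spec)


class TestLimitingCases:
    def test_radius_beyond_diameter_gives_whole_alignment_score(self, helix10_fixture):
        """Window = everything ⇒ every residue carries the global statistic."""
        fx = helix10_fixture
        result = run_window_analysis(
            fx.structure, fx.alignment, fx.reference, "seg-sites",
            NeighborQueryConfig(radius=1e6),
        )
        from structwin.popgen import segregating_sites

        expected = float(segregating_sites(fx.alignment))
        assert set(result.scores.values()) == {expected}
        assert set(result.window_sizes.values()) == {10}

    def test_radius_below_spacing_numeric_mean_is_own_value(self, helix10_fixture):
        """Window = self ⇒ the numeric mean is each residue's own value."""
        fx = helix10_fixture
        table = NumericTable(values={i: float(i) * 1.5 for i in range(1, 11)})
        result = run_window_analysis(
            fx.structure, table, fx.reference, "mean",
            NeighborQueryConfig(radius=0.001),
        )
        for rid, score in result.scores.items():
            assert score == pytest.approx(rid.number * 1.5)
            assert result.window_sizes[rid] == 1

    def test_min_data_thresholds_to_null(self, helix10_fixture):
        fx = helix10_fixture
        table = NumericTable(values={1: 1.0})  # only residue 1 has data
        fn = get_function("mean", min_data=2)
        result = run_window_analysis(
            fx.structure, table, fx.reference, fn, NeighborQueryConfig(radius=0.001)
        )
        assert all(v is None for v in result.scores.values())


class TestBruteForceEquivalence:
    @pytest.mark.parametrize(
        "geometry,stat", [("ideal-helix", "tajimas-d"), ("two-cluster", "pi")]
    )
    def test_matches_reference_pipeline(self, geometry, stat):
        """Engine output equals the straight-line no-index pipeline (1e-9)."""
        spec = FixtureSpec(
            n_residues=40,
            n_sequences=12,
            geometry=geometry,
            mutation_model="planted-balanced-cluster",
            cluster_residues=frozenset(range(8, 13)),
            seed=17,
        )
        fx = make_fixture(spec)
        radius = 12.0
        result = run_window_analysis(
            fx.structure, fx.alignment, fx.reference, stat,
            NeighborQueryConfig(radius=radius),
        )
        rmap = build_residue_map(fx.structure, fx.alignment, fx.reference)
        expected = oracle_window_scores(
            fx.structure, fx.alignment.rows, rmap, radius, stat=stat
        )
        assert set(result.scores) == set(expected)
        for rid, exp in expected.items():
            got = result.scores[rid]
            if exp is None:
                assert got is None
            else:
                assert got == pytest.approx(exp, abs=1e-9)

    def test_window_sizes_monotone_in_radius(self, helix10_fixture):
        fx = helix10_fixture
        sizes = []
        for radius in (4.0, 8.0, 16.0, 1e6):
            result = run_window_analysis(
                fx.structure, fx.alignment, fx.reference, "pi",
                NeighborQueryConfig(radius=radius),
            )
            sizes.append(result.window_sizes)
        for small, big in zip(sizes, sizes[1:]):
            assert all(small[rid] <= big[rid] for rid in small)


class TestPlantedClusterDiscovery:
    def test_cluster_residues_score_higher(self, planted_fixture):
        """The balanced-polymorphism patch stands out at radius 15 Å."""
        fx = planted_fixture
        result = run_window_analysis(
            fx.structure, fx.alignment, fx.reference, "tajimas-d",
            NeighborQueryConfig(radius=15.0),
        )
        cluster = fx.spec.cluster_residues
        inside = [v for rid, v in result.defined().items() if rid.number in cluster]
        outside = [v for rid, v in result.defined().items() if rid.number not in cluster]
        assert np.mean(inside) > np.mean(outside)


class TestValidationAndErrors:
    def test_function_kind_must_match_data(self, helix10_fixture):
        fx = helix10_fixture
        with pytest.raises(InputError, match="expects"):
            run_window_analysis(
                fx.structure, NumericTable(values={1: 1.0}), fx.reference,
                "tajimas-d", NeighborQueryConfig(radius=5.0),
            )

    def test_unknown_function_name(self):
        with pytest.raises(InputError, match="unknown function"):
            get_function("no-such-statistic")

    def test_raising_scorer_reports_central_residue(self, helix10_fixture):
        fx = helix10_fixture

        def boom(sub):
            raise ValueError("bad window")

        fn = ScoringFunction("boom", "dna-alignment", boom)
        with pytest.raises(ScoringError, match=r"A/1"):
            run_window_analysis(
                fx.structure, fx.alignment, fx.reference, fn,
                NeighborQueryConfig(radius=5.0),
            )


class TestExport:
    def test_tsv_rows_and_null_rendering(self, helix10_fixture, tmp_path):
        fx = helix10_fixture
        table = NumericTable(values={1: 1.0})
        fn = get_function("mean", min_data=2)
        result = run_window_analysis(
            fx.structure, table, fx.reference, fn, NeighborQueryConfig(radius=0.001)
        )
        p = tmp_path / "r.tsv"
        write_tsv(result, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "chain\tresnum\ticode\tscore\twindow_size"
        assert len(lines) == 11
        assert all(l.split("\t")[3] == "" for l in lines[1:])  # null → empty field

    def test_json_roundtrip_restores_scores(self, helix10_fixture, tmp_path):
        fx = helix10_fixture
        result = run_window_analysis(
            fx.structure, fx.alignment, fx.reference, "tajimas-d",
            NeighborQueryConfig(radius=8.0),
        )
        p = tmp_path / "r.json"
        write_json(result, p)
        back = read_json_scores(p)
        assert set(back) == set(result.scores)
        for rid, v in result.scores.items():
            if v is None:
                assert back[rid] is None
            else:
                assert back[rid] == pytest.approx(v)

    def test_exports_are_deterministic(self, helix10_fixture, tmp_path):
        fx = helix10_fixture
        paths = []
        for tag in ("a", "b"):
            result = run_window_analysis(
                fx.structure, fx.alignment, fx.reference, "tajimas-d",
                NeighborQueryConfig(radius=8.0),
            )
            tsv, js = tmp_path / f"{tag}.tsv", tmp_path / f"{tag}.json"
            export_results(result, structure=fx.structure, tsv_path=tsv, json_path=js)
            paths.append((tsv.read_bytes(), js.read_bytes()))
        assert paths[0] == paths[1]

    def test_pdb_export_carries_scores(self, helix10_fixture, tmp_path):
        fx = helix10_fixture
        result = run_window_analysis(
            fx.structure, fx.alignment, fx.reference, "seg-sites",
            NeighborQueryConfig(radius=1e6),
        )
        pdb = tmp_path / "r.pdb"
        export_results(result, structure=fx.structure, pdb_path=pdb)
        score = next(iter(result.scores.values()))
        for line in pdb.read_text().splitlines():
            if line.startswith("ATOM"):
                assert float(line[60:66]) == pytest.approx(score, abs=5e-3)


class TestHomodimer:
    def test_both_protomers_scored_and_columns_duplicated(self):
        """A window spanning both chains counts each residue's codon once per
        residue, so the sub-alignment doubles in width."""
        spec = FixtureSpec(n_residues=6, n_sequences=6, seed=41, mutation_rate=0.5)
        fx = make_fixture(spec)
        # second protomer: same residues shifted by 100 Å, chain B
        from structwin.structures import Atom, Residue, Structure

        chains = {"A": fx.structure.chains["A"], "B": []}
        for res in fx.structure.chains["A"]:
            atoms = [
                Atom(name=a.name, element=a.element, coord=a.coord + np.array([100.0, 0, 0]),
                     occupancy=a.occupancy, bfactor=a.bfactor)
                for a in res.atoms
            ]
            chains["B"].append(
                Residue(id=ResidueId("B", res.id.number), resname=res.resname, atoms=atoms)
            )
        dimer = Structure(id="dimer", chains=chains)

        near = run_window_analysis(
            dimer, fx.alignment, fx.reference, "pi", NeighborQueryConfig(radius=1e6)
        )
        assert set(near.window_sizes.values()) == {12}
        rmap = build_residue_map(dimer, fx.alignment, fx.reference)
        from structwin.seqalign import window_subalignment

        sub = window_subalignment(
            fx.alignment, rmap, list(near.scores), gap_policy="pairwise"
        )
        assert sub.length == 2 * fx.alignment.length
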