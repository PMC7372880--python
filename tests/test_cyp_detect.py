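"""Motif scanning, CYP curation and physicochemical properties."""

import numpy as np
import pytest

from cypminer.cyp_detect import (
    MotifModel,
    RESIDUE_MASS,
    WATER_MASS,
    call_cyp,
    default_models,
    heme_cysteine_offset,
    isoelectric_point,
    molecular_weight,
    net_charge,
    scan_motif,
)
from cypminer.orfmine import find_orfs
from cypminer.seqio import NucleotideRecord, ProteinRecord, reverse_complement


class TestScanMotif:
    def test_exxr_hit(self):
        prot = ProteinRecord("p", "AAAAEAIRMAAAA")
        model = default_models()["ExxR"]
        hits = scan_motif(prot, model)
        assert [(h.start, h.mismatches) for h in hits] == [(4, 0)]
        assert hits[0].matched == "EAIR"

    def test_heme_invariant_cysteine_required(self):
        model = default_models()["heme"]
        # perfect window except C -> no hit
        prot = ProteinRecord("p", "AAAFAAGARAXAGAAA".replace("X", "A"))
        assert scan_motif(prot, model) == []

    def test_x_never_matches(self):
        model = MotifModel.from_string("m", "AG", max_mismatches=0)
        assert scan_motif(ProteinRecord("p", "AXAG"), model)[0].start == 2

    def test_planted_coordinates_recovered(self, small_sim):
        """Every planted motif instance is among the scan hits at the
        expected anchor (heme detection anchors one residue into the
        planted window)."""
        _, res = small_sim
        truth = res.truth.set_index("id")
        models = default_models()
        for p in res.proteins:
            row = truth.loc[p.id]
            if not row.full_length:
                continue
            coords = dict(x.split(":") for x in row.motif_coords.split(";"))
            for motif, model in models.items():
                s, _ = map(int, coords[motif].split("-"))
                expected = s + 1 if motif == "heme" else s
                starts = [h.start for h in scan_motif(p, model)]
                assert expected in starts, (p.id, motif)


class TestCallCyp:
    def _full_call(self, res, rec_id):
        contig = next(t for t in res.transcripts if t.id == rec_id)
        orfs = find_orfs(contig, min_aa=100)
        models = default_models()
        return [call_cyp(o.protein, o, models) for o in orfs]

    def test_truth_full_length_protein(self, small_sim):
        _, res = small_sim
        truth = res.truth.set_index("id")
        rid = truth.index[truth.full_length][0]
        calls = self._full_call(res, rid)
        best = next(c for c in calls if c.full_length)
        assert best.cyp_like and best.failure_reasons == []
        assert best.pI is not None and best.mw_kda is not None

    def test_truncated_protein_too_short(self, small_sim):
        _, res = small_sim
        truth = res.truth.set_index("id")
        rid = truth.index[truth.full_length][0]
        p = next(pr for pr in res.proteins if pr.id == rid)
        short = ProteinRecord("short", p.seq[-350:])
        call = call_cyp(short, None, default_models())
        assert call.cyp_like
        assert not call.full_length
        assert "too_short" in call.failure_reasons
        assert "no_start" in call.failure_reasons

    def test_orientation_invariance(self, small_sim):
        """Reverse-complementing the contig yields the same verdict via the
        minus-strand ORF."""
        _, res = small_sim
        truth = res.truth.set_index("id")
        rid = truth.index[truth.full_length][0]
        contig = next(t for t in res.transcripts if t.id == rid)
        flipped = NucleotideRecord("flip", reverse_complement(contig.seq))
        models = default_models()
        calls = [
            call_cyp(o.protein, o, models)
            for o in find_orfs(flipped, min_aa=100)
        ]
        best = next(c for c in calls if c.full_length)
        assert best.orf.strand == "-"
        fwd_best = next(
            c for c in self._full_call(res, rid) if c.full_length
        )
        assert best.protein.seq == fwd_best.protein.seq

    def test_decoys_never_cyp_like(self, small_sim):
        _, res = small_sim
        models = default_models()
        decoys = [t for t in res.transcripts if t.id.startswith("decoy")]
        assert decoys
        for t in decoys:
            for o in find_orfs(t, min_aa=100):
                assert not call_cyp(o.protein, o, models).cyp_like

    def test_heme_offset_definition(self):
        models = default_models()
        # protein of length 100 with heme hit whose C sits at index 50
        hit_start = 50 - models["heme"].invariant[0]
        from cypminer.cyp_detect import MotifHit

        hit = MotifHit("heme", hit_start, hit_start + 10, "", 0)
        assert heme_cysteine_offset(100, hit, models["heme"]) == 50


class TestMolecularWeight:
    def test_single_glycine(self):
        assert molecular_weight("G") * 1000 == pytest.approx(75.07, abs=0.01)

    def test_diglycine_one_water(self):
        assert molecular_weight("GG") * 1000 == pytest.approx(132.12, abs=0.01)

    def test_matches_atomic_sum_oracle(self, rng):
        seq = "".join(rng.choice(list(RESIDUE_MASS), 120))
        expected = sum(RESIDUE_MASS[c] for c in seq) + WATER_MASS
        assert molecular_weight(seq) == pytest.approx(expected / 1000)

    def test_ambiguous_residue_errors(self):
        with pytest.raises(ValueError):
            molecular_weight("GXG")
        with pytest.raises(ValueError):
            molecular_weight("")


class TestIsoelectricPoint:
    def test_half_protonation_at_sidechain_pka(self):
        """At pH equal to a lone ionizable side chain's pKa the group is
        half protonated."""
        from cypminer.cyp_detect import PKA

        # glycine backbone with one aspartate; at pH == pKa(D) its charge
        # contribution is exactly -0.5
        contribution = -1.0 / (1.0 + 10 ** (PKA["D"] - PKA["D"]))
        assert contribution == pytest.approx(-0.5)

    def test_basic_peptide_above_acidic_peptide(self):
        assert isoelectric_point("KKKKKK") > isoelectric_point("DDDDDD")

    def test_bisection_matches_grid_scan_oracle(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
            grid = np.arange(0.0, 14.0, 0.001)
            charges = np.array([net_charge(seq, ph) for ph in grid])
            pi_grid = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq) == pytest.approx(pi_grid, abs=0.01)
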