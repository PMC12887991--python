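"""Modification-site remapping, classification, FLR, NSAF, PTM vectors."""

from collections import Counter

import numpy as np
import pytest

from conftest import make_db
from panatlas.ptm import (
    abundance_vs_modification,
    classify_events,
    compute_nsaf,
    estimate_phospho_flr,
    per_residue_breakdown,
    per_run_ptm_vector,
    remap_modification_sites,
)
from panatlas.records import (
    Engine,
    MergedPsm,
    ModificationEvent,
    NsafRecord,
    PeptideEvidence,
    Provenance,
    PsmRecord,
    Tier,
    TierAssignment,
)


def merged(peptidoform, spectrum_id, run_id="r1"):
    rec = PsmRecord(run_id=run_id, spectrum_id=spectrum_id, engine=Engine.CLOSED,
                    peptidoform=peptidoform, charge=2, score=50.0, q_value=1e-4,
                    loc_score=30.0)
    return MergedPsm(psm=rec, provenance=Provenance.CLOSED_ONLY)


def tier(gid, db, t=Tier.CANONICAL):
    return TierAssignment(group_id=gid,
                          representative_accession=db.records[gid].accession,
                          tier=t, n_unique_peptides=2, n_shared_peptides=0,
                          in_core_proteome=False)


def event(gid, pos, residue, mod, support=1, runs=("r1",)):
    return ModificationEvent(group_id=gid, position=pos, residue=residue,
                             mod_name=mod, psm_support=support,
                             runs_observed=frozenset(runs))


class TestRemap:
    # protein: positions 1..9 = WWWDDDEEE, 10..18 = ASTWNQHIL (peptide site)
    DB = [("P1", "WWWDDDEEEKASTWNQHIL", "A"),
          ("P2", "MMMMGGGGHHHHLLLLNNN", "A")]

    def test_coordinate_arithmetic(self):
        db = make_db(self.DB)
        tiers = [tier(0, db), tier(1, db, Tier.NOT_OBSERVED)]
        events = remap_modification_sites([merged("AS[Phospho]TWNQHIL", "s1")],
                                          tiers, db)
        assert len(events) == 1
        assert events[0].position == 12  # peptide starts at 11; S is 2nd residue
        assert events[0].residue == "S"

    def test_multi_canonical_mapping_contributes_nothing(self):
        seq = "WWWDDDEEEKASTWNQHIL"
        db = make_db([("P1", seq, "A"), ("P2", "MMMM" + seq, "A")])
        tiers = [tier(0, db), tier(1, db)]
        events = remap_modification_sites([merged("AS[Phospho]TWNQHIL", "s1")],
                                          tiers, db)
        assert events == []

    def test_non_canonical_groups_are_ignored_for_mapping(self):
        seq = "WWWDDDEEEKASTWNQHIL"
        db = make_db([("P1", seq, "A"), ("P2", "MMMM" + seq, "A")])
        tiers = [tier(0, db), tier(1, db, Tier.UNCERTAIN)]
        events = remap_modification_sites([merged("AS[Phospho]TWNQHIL", "s1")],
                                          tiers, db)
        assert len(events) == 1  # unique among *canonical* groups

    def test_aggregation_over_psms_and_runs(self):
        db = make_db(self.DB)
        tiers = [tier(0, db), tier(1, db, Tier.NOT_OBSERVED)]
        psms = [merged("AS[Phospho]TWNQHIL", "s1", "r1"),
                merged("AS[Phospho]TWNQHIL", "s2", "r1"),
                merged("AS[Phospho]TWNQHIL", "s3", "r2")]
        events = remap_modification_sites(psms, tiers, db)
        assert len(events) == 1
        assert events[0].psm_support == 3
        assert events[0].runs_observed == frozenset({"r1", "r2"})

    def test_site_coordinates_always_match_protein(self, synth_small):
        """Global invariant on a full synthetic scenario."""
        from panatlas.inference import assign_tiers, compute_evidence
        from panatlas.merge import filter_localization, filter_open_psms, merge_searches

        s = synth_small
        closed = filter_localization(s["closed"], 20)
        open_ = filter_localization(filter_open_psms(s["open"], 0.0005), 20)
        merged_psms = merge_searches(closed, open_)
        ev, _ = compute_evidence(merged_psms, s["db"])
        tiers = assign_tiers(ev, s["db"], "S01")
        events = remap_modification_sites(merged_psms, tiers, s["db"])
        assert events  # scenario plants modifications
        for e in events:
            assert s["db"].records[e.group_id].sequence[e.position - 1] == e.residue

    def test_event_counts_invariant_to_psm_order(self):
        db = make_db(self.DB)
        tiers = [tier(0, db), tier(1, db, Tier.NOT_OBSERVED)]
        psms = [merged("AS[Phospho]TWNQHIL", "s1"),
                merged("ASTWN[Deamidated]QHIL", "s2"),
                merged("AS[Phospho]TWNQHIL", "s3", "r2")]
        forward = remap_modification_sites(psms, tiers, db)
        backward = remap_modification_sites(psms[::-1], tiers, db)
        assert forward == backward


class TestClassifyEvents:
    MAP = {"Phospho": ["Post-translational"],
           "Methyl": ["Post-translational", "Chemical derivative"],
           "Oxidation": ["Artefact"]}

    def test_single_multi_and_unknown_classes(self):
        events = [event(0, 1, "S", "Phospho"), event(0, 2, "K", "Methyl"),
                  event(0, 3, "W", "Wobblyl")]
        classified, counts = classify_events(events, self.MAP)
        assert [e.unimod_class for e in classified] == [
            "Post-translational", "Other", "Unclassified"]
        assert counts == Counter({"Post-translational": 1, "Other": 1,
                                  "Unclassified": 1})

    def test_empty_map_errors(self):
        with pytest.raises(ValueError):
            classify_events([event(0, 1, "S", "Phospho")], {})


class TestPerResidueBreakdown:
    def test_counts_and_conservation(self):
        events = [event(0, 1, "S", "Phospho"), event(0, 5, "S", "Phospho"),
                  event(1, 3, "S", "Phospho"), event(0, 9, "T", "Phospho"),
                  event(0, 2, "M", "Oxidation")]
        breakdown = per_residue_breakdown(events, "Phospho")
        assert breakdown == {"S": 3, "T": 1}
        assert sum(breakdown.values()) == 4

    def test_unknown_modification_empty(self):
        assert per_residue_breakdown([event(0, 1, "S", "Phospho")], "Nope") == {}

    def test_planted_per_residue_counts_recovered(self):
        rng = np.random.default_rng(7)
        planted = {"S": 5, "T": 3, "Y": 2}
        events = []
        pos = 1
        for res, n in planted.items():
            for _ in range(n):
                events.append(event(0, pos, res, "Phospho"))
                pos += 1
        order = rng.permutation(len(events))
        assert per_residue_breakdown([events[i] for i in order], "Phospho") == planted


class TestPhosphoFlr:
    def _db_with_composition(self):
        # 600 residues: 54 A (9%), 108 S (18%), rest G/L/V filler
        seq = "A" * 54 + "S" * 108 + "G" * 200 + "L" * 138 + "V" * 100
        db = make_db([("P1", seq, "A")])
        return db, [tier(0, db)]

    def test_zero_alanine_sites_gives_zero(self):
        db, tiers = self._db_with_composition()
        events = [event(0, 55 + i, "S", "Phospho") for i in range(10)]
        assert estimate_phospho_flr(events, db, tiers) == 0.0

    def test_stated_estimator_arithmetic(self):
        db, tiers = self._db_with_composition()
        events = [event(0, 1, "A", "Phospho")]
        events += [event(0, 55 + i, "S", "Phospho") for i in range(100)]
        # (1/0.09) / (100/0.18) = 0.02
        assert estimate_phospho_flr(events, db, tiers) == pytest.approx(0.02)

    def test_alanine_without_sty_errors(self):
        db, tiers = self._db_with_composition()
        with pytest.raises(ValueError):
            estimate_phospho_flr([event(0, 1, "A", "Phospho")], db, tiers)


class TestNsaf:
    DB = [("P1", "A" * 93 + "CDEFGHK", "A"),       # length 100
          ("P2", "M" * 43 + "WYWYWYK", "A")]       # length 50

    def _evidence(self):
        return [PeptideEvidence("CDEFGHK", frozenset({0}), 1, 50.0),
                PeptideEvidence("WYWYWYK", frozenset({1}), 1, 50.0),
                PeptideEvidence("SHAREDPEP", frozenset({0, 1}), 1, 50.0)]

    def test_direct_formula(self):
        db = make_db(self.DB)
        psms = [merged("CDEFGHK", f"s{i}") for i in range(10)]
        psms += [merged("OTHERPEPTIDE", f"o{i}") for i in range(990)]
        records = compute_nsaf(psms, self._evidence(), db)
        rec = next(r for r in records if r.group_id == 0)
        assert rec.unique_psm_count == 10
        assert rec.nsaf == pytest.approx((10 / 100) / 1000)

    def test_shared_peptides_count_for_nobody(self):
        db = make_db(self.DB)
        psms = [merged("SHAREDPEP", f"s{i}") for i in range(5)]
        assert compute_nsaf(psms, self._evidence(), db) == []

    def test_scale_invariance(self):
        db = make_db(self.DB)
        base = [merged("CDEFGHK", f"s{i}") for i in range(4)]
        base += [merged("WYWYWYK", f"w{i}") for i in range(8)]
        doubled = base + [merged(m.peptidoform, m.spectrum_id + "x") for m in base]
        nsaf1 = {r.group_id: r.nsaf for r in compute_nsaf(base, self._evidence(), db)}
        nsaf2 = {r.group_id: r.nsaf for r in compute_nsaf(doubled, self._evidence(), db)}
        assert nsaf1 == pytest.approx(nsaf2)


class TestAbundanceVsModification:
    def _nsaf(self, values):
        return [NsafRecord(gid, "r1", 1, 100, v) for gid, v in enumerate(values)]

    def test_sites_proportional_to_abundance_gives_positive_rho(self):
        rng = np.random.default_rng(8)
        n = 30
        abundance = np.sort(rng.lognormal(0, 1, n))
        events = []
        pos = 1
        for gid in range(n):
            for _ in range(gid // 3):  # site count grows with abundance rank
                events.append(event(gid, pos, "S", "Phospho"))
                pos += 1
        table, rho = abundance_vs_modification(self._nsaf(abundance), events)
        assert rho > 0

    def test_constant_site_counts_give_zero(self):
        events = [event(gid, 1, "S", "Phospho") for gid in range(5)]
        _table, rho = abundance_vs_modification(self._nsaf([1, 2, 3, 4, 5]), events)
        assert rho == 0.0

    def test_below_three_proteins_omits_correlation(self):
        events = [event(0, 1, "S", "Phospho")]
        table, rho = abundance_vs_modification(self._nsaf([1.0]), events)
        assert rho is None and len(table) == 1


class TestPerRunPtmVector:
    def test_counts_per_run(self):
        psms = [merged("AS[Phospho]TK", f"s{i}", "r1") for i in range(5)]
        psms += [merged("M[Oxidation]NK", f"o{i}", "r1") for i in range(2)]
        psms += [merged("PLAINPEP", "p1", "r2")]
        matrix = per_run_ptm_vector([], psms)
        assert matrix.loc["r1", "Phospho"] == 5
        assert matrix.loc["r1", "Oxidation"] == 2
        assert (matrix.loc["r2"] == 0).all()

    def test_column_sums_equal_global_counts(self):
        rng = np.random.default_rng(9)
        psms = []
        for i in range(60):
            run = f"r{int(rng.integers(3))}"
            form = ["AS[Phospho]TK", "M[Oxidation]NK", "PLAINPEP"][int(rng.integers(3))]
            psms.append(merged(form, f"s{i}", run))
        matrix = per_run_ptm_vector([], psms)
        global_counts = Counter()
        for m in psms:
            for _pos, name in m.psm.modifications():
                global_counts[name] += 1
        for mod in matrix.columns:
            assert matrix[mod].sum() == global_counts[mod]
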