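"""CBC/hCBC classification, motif checks, pseudogene screening, chimera scan."""

import itertools

import numpy as np
import pytest

from itshybrid import polymorphism as poly
from itshybrid import structure_qc as qc
from itshybrid.structure_qc import ChangeClass, Verdict
from itshybrid.types import AlignedSet, SequenceRecord, StructureTemplate


class TestClassifyBaseChange:
    def test_cbc(self, hairpin_template):
        # G-C -> A-T(U): both partners change, bond retained
        c = qc.classify_base_change(hairpin_template, 1, "G", "A", ("C", "T"))
        assert c.klass == ChangeClass.CBC

    def test_hcbc_wobble(self, hairpin_template):
        # G-C -> G-T(U): one partner changes, wobble bond retained
        c = qc.classify_base_change(hairpin_template, 1, "G", "G", ("C", "T"))
        assert c.klass == ChangeClass.HCBC

    def test_non_compensatory(self, hairpin_template):
        c = qc.classify_base_change(hairpin_template, 1, "G", "A", "C")
        assert c.klass == ChangeClass.NON_COMPENSATORY

    def test_unpaired_loop_position(self, hairpin_template):
        c = qc.classify_base_change(hairpin_template, 7, "A", "G")
        assert c.klass == ChangeClass.UNPAIRED and c.partner is None

    def test_partner_state_at_unpaired_site_is_error(self, hairpin_template):
        with pytest.raises(ValueError, match="unpaired"):
            qc.classify_base_change(hairpin_template, 7, "A", "G", "C")

    def test_wobble_off_makes_gu_non_compensatory(self, hairpin_template):
        c = qc.classify_base_change(
            hairpin_template, 1, "G", "G", ("C", "T"), wobble=False
        )
        assert c.klass == ChangeClass.NON_COMPENSATORY

    def test_exhaustive_truth_table(self, hairpin_template):
        # all 16 x 16 (from-pair, to-pair) transitions at a paired site,
        # against a literal bond-table oracle
        bonds = {
            ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
        }
        for old in itertools.product("ACGT", repeat=2):
            for new in itertools.product("ACGT", repeat=2):
                got = qc.classify_base_change(
                    hairpin_template, 1, old[0], new[0], (old[1], new[1])
                )
                if old == new:
                    expected = ChangeClass.SILENT
                elif new in bonds:
                    n_changed = (old[0] != new[0]) + (old[1] != new[1])
                    expected = ChangeClass.CBC if n_changed == 2 else ChangeClass.HCBC
                else:
                    expected = ChangeClass.NON_COMPENSATORY
                assert got.klass == expected, (old, new, got.klass)
                assert got.from_pair == old and got.to_pair == new

    def test_hcbc_implies_bond_retained(self, hairpin_template):
        for old in itertools.product("ACGT", repeat=2):
            for new in itertools.product("ACGT", repeat=2):
                got = qc.classify_base_change(
                    hairpin_template, 1, old[0], new[0], (old[1], new[1])
                )
                if got.klass in (ChangeClass.HCBC, ChangeClass.CBC):
                    assert qc.is_bond(got.to_pair)


class TestSummarize:
    def _sites(self, cols_states):
        return [
            poly.PolymorphicSite(c, None, {"g": frozenset(s)}) for c, s in cols_states
        ]

    def test_empty_site_list(self, hairpin_template):
        table = qc.summarize_change_classes([], hairpin_template)
        assert table.to_numpy().sum() == 0

    def test_single_hcbc_site(self, hairpin_template):
        # template pos 1 is G paired with C at 14; variant T keeps a G?:
        # G->T at position 1 gives T-C (no bond) => non-compensatory;
        # position 14 C->T gives G-T wobble => hCBC
        table = qc.summarize_change_classes(
            self._sites([(14, "CT")]), hairpin_template
        )
        assert table["hCBC"].sum() == 1 and table.to_numpy().sum() == 1

    def test_counts_partition_sites(self, hairpin_template):
        sites = self._sites([(1, "GA"), (7, "AG"), (14, "CT"), (8, "AC")])
        table = qc.summarize_change_classes(sites, hairpin_template)
        assert table.to_numpy().sum() == len(sites)

    def test_unmapped_site_is_error(self, hairpin_template):
        with pytest.raises(ValueError, match="not mapped"):
            qc.summarize_change_classes(self._sites([(99, "AC")]), hairpin_template)


class TestMotifs:
    def test_synthetic_consensus_passes_all_motifs(self, study):
        checks = qc.check_motifs(study.maternal_pool[-1], study.regions)
        assert all(c.passed for c in checks)

    def test_substitution_in_m2_fails_only_m2(self, study):
        rec = study.maternal_pool[-1]
        sub = qc.find_motif(rec.seq, qc.DEFAULT_MOTIFS["M2"]["pattern"])[0]
        seq = list(rec.seq)
        seq[sub - 1] = "A" if seq[sub - 1] != "A" else "C"
        mutated = SequenceRecord("mut", "".join(seq))
        checks = {c.motif_id: c for c in qc.check_motifs(mutated, study.regions)}
        assert not checks["M2"].passed
        assert checks["M1"].passed and checks["M3"].passed
        assert checks["ITS1_angiosperm"].passed

    def test_iupac_pattern_position_matches_expansion(self):
        # pattern R matches observed G
        assert qc.find_motif("AAGAA", "ARA") == (2, 0)

    def test_missing_region_reported_failed_not_error(self, study):
        from itshybrid.types import RegionAnnotation

        regions = RegionAnnotation(
            {"ITS1": (1, 241), "5.8S": (242, 241), "ITS2": (242, 617)}
        )
        checks = {c.motif_id: c for c in qc.check_motifs(study.maternal_pool[-1], regions)}
        assert not checks["M1"].passed and not checks["M3"].passed


class TestScreenPseudogenes:
    def _toy_library(self, study, edits):
        cons = poly.call_consensus(study.maternal_pool, 0.25, "cons")
        clones = []
        for i, cols in enumerate(edits):
            seq = list(study.maternal_pool[-1].seq)
            for col, base in cols:
                seq[col - 1] = base
            clones.append(SequenceRecord(f"c{i}", "".join(seq), "lib"))
        return AlignedSet.from_records(clones), cons

    def test_clone_identical_to_consensus_is_ok(self, study):
        lib, cons = self._toy_library(study, [[], []])
        reports = qc.screen_pseudogenes(lib, cons, study.regions)
        assert all(r.verdict == Verdict.OK for r in reports)

    def test_one_58s_substitution_flags_nonfunctional(self, study):
        col = study.regions.spans["5.8S"][0] + 30
        base = "A" if study.maternal_pool[-1].seq[col - 1] != "A" else "G"
        lib, cons = self._toy_library(study, [[], [(col, base)]])
        reports = qc.screen_pseudogenes(lib, cons, study.regions)
        assert reports[0].verdict == Verdict.OK
        assert reports[1].verdict == Verdict.PUTATIVE_NONFUNCTIONAL
        assert reports[1].n_58S_substitutions == 1

    def test_verdict_monotone_under_added_58s_substitution(self, study):
        # adding a 5.8S substitution can never clear a clone
        col = study.regions.spans["5.8S"][0] + 30
        base = "A" if study.maternal_pool[-1].seq[col - 1] != "A" else "G"
        spacer_col = 10
        spacer_base = "A" if study.maternal_pool[-1].seq[9] != "A" else "G"
        lib1, cons = self._toy_library(study, [[], [(spacer_col, spacer_base)]])
        lib2, _ = self._toy_library(
            study, [[], [(spacer_col, spacer_base), (col, base)]]
        )
        v1 = qc.screen_pseudogenes(lib1, cons, study.regions)[1].verdict
        v2 = qc.screen_pseudogenes(lib2, cons, study.regions)[1].verdict
        assert v2 == Verdict.PUTATIVE_NONFUNCTIONAL
        assert not (v1 == Verdict.PUTATIVE_NONFUNCTIONAL and v2 == Verdict.OK)

    def test_singleton_noncompensatory_flagged_artifact(self, study):
        # find a paired spacer column whose disruption is non-compensatory
        template = study.template
        partner = template.partner_map()
        col = next(
            c
            for c in range(study.regions.spans["ITS1"][0], study.regions.spans["ITS1"][1])
            if c in partner and template.seq[c - 1] == "G"
        )
        lib, cons = self._toy_library(study, [[], [], [(col, "C")]])  # G->C breaks pair
        reports = qc.screen_pseudogenes(
            lib, cons, study.regions, template=template
        )
        assert reports[2].verdict == Verdict.PUTATIVE_ARTIFACT

    def test_missing_58s_span_is_error(self, study):
        from itshybrid.types import RegionAnnotation

        lib, cons = self._toy_library(study, [[], []])
        bad = RegionAnnotation({"ITS1": (1, 241), "5.8S": (242, 241), "ITS2": (242, 617)})
        with pytest.raises(ValueError, match="5.8S"):
            qc.screen_pseudogenes(lib, cons, bad)


class TestChimeraScan:
    def _parents(self):
        L = 400
        rng = np.random.default_rng(12)
        a = rng.choice(list("ACGT"), L)
        b = a.copy()
        # 20 informative sites: 10 left, 10 right
        inf = list(range(10, 200, 19)) + list(range(210, 395, 19))
        for c in inf:
            b[c] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[c]]
        return (
            SequenceRecord("A", "".join(a)),
            SequenceRecord("B", "".join(b)),
            sorted(inf),
        )

    def test_detects_planted_breakpoint(self):
        pa, pb, inf = self._parents()
        bp = 205
        q = SequenceRecord("q", pa.seq[:bp] + pb.seq[bp:])
        report = qc.chimera_scan(q, pa, pb, reps=499, seed=3)
        assert report is not None
        # breakpoint must fall within +-1 informative site of the junction
        left_of_bp = [c + 1 for c in inf if c + 1 <= bp]
        assert abs(left_of_bp.index(report.position) - (len(left_of_bp) - 1)) <= 1

    def test_max_chisq_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        vec = rng.integers(0, 2, size=25)
        got_chi2, got_k = qc._max_chisq(vec)
        best = (0.0, 0)
        n = len(vec)
        for k in range(1, n):
            la = int(vec[:k].sum())
            lb = k - la
            ra = int(vec[k:].sum())
            rb = n - k - ra
            obs = np.array([[la, lb], [ra, rb]], dtype=float)
            row = obs.sum(1, keepdims=True)
            col = obs.sum(0, keepdims=True)
            if (row == 0).any() or (col == 0).any():
                continue
            exp = row @ col / n
            chi2 = float(((obs - exp) ** 2 / exp).sum())
            if chi2 > best[0]:
                best = (chi2, k)
        assert got_chi2 == pytest.approx(best[0]) and got_k == best[1]

    def test_pure_parental_query_not_flagged(self):
        pa, pb, _ = self._parents()
        assert qc.chimera_scan(pa, pa, pb, reps=99, seed=1) is None

    def test_identical_parents_is_error(self):
        pa, _, _ = self._parents()
        with pytest.raises(ValueError, match="no informative sites"):
            qc.chimera_scan(pa, pa, pa, reps=99, seed=1)

    def test_few_informative_sites_warns_and_returns_none(self):
        pa = SequenceRecord("A", "AAAAAAAAAA")
        pb = SequenceRecord("B", "AAAAAAAAAC")
        q = SequenceRecord("q", "AAAAAAAAAC")
        with pytest.warns(UserWarning, match="informative"):
            assert qc.chimera_scan(q, pa, pb, reps=99, seed=1) is None

    def test_type_one_error_controlled(self):
        # non-chimeric queries built by iid per-site parent choice: the scan
        # at alpha=0.05 must reject at most ~alpha of them
        pa, pb, inf = self._parents()
        rng = np.random.default_rng(77)
        rejections = 0
        n_trials = 60
        for t in range(n_trials):
            seq = list(pa.seq)
            for c in inf:
                if rng.random() < 0.5:
                    seq[c] = pb.seq[c]
            q = SequenceRecord("q", "".join(seq))
            if qc.chimera_scan(q, pa, pb, reps=199, seed=1000 + t) is not None:
                rejections += 1
        assert rejections / n_trials <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_trials)
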