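"""Mechanistic simulator: nicking model, DSP/SSP recovery rules, cohorts."""

from dataclasses import replace

import numpy as np
import pytest

from cffrag.io import build_profile
from cffrag.profile import detect_subpeaks, periodicity, stagger_offset
from cffrag.simulate import (
    CLASSES,
    DEFAULT_MODEL,
    CohortParams,
    Molecule,
    MoleculeSet,
    NucleosomeModel,
    dsp_readout,
    dsp_segments,
    get_preset,
    malignant_mixture,
    simulate_cohort,
    simulate_molecules,
    ssp_pieces,
    ssp_readout,
)

# Deterministic readout rules: no peel-off loss, no short-piece attrition,
# no end fraying — used wherever a test checks exact mechanism counts.
EXACT_MODEL = replace(
    DEFAULT_MODEL,
    peel_discard_prob=0.0,
    ssp_min_len=1,
    ssp_reliable=1,
    ssp_survival_full_len=1,
    ssp_end_smear=0.0,
    ssp_long_decay=0.0,
)


def nick_free_params(**over):
    base = get_preset("healthy-7")
    weights = dict(zip(CLASSES, base.weights))
    weights["HIGH_MW"] = 0.0
    total = sum(weights.values())
    return replace(
        base,
        weights=tuple(w / total for w in weights.values()),
        p_site_nick=0.0,
        jitter_sd=0.0,
        **over,
    )


def random_molecules(n, rng, max_len=600):
    mols = []
    for _ in range(n):
        L = int(rng.integers(40, max_len))
        nw = int(rng.integers(0, 6))
        nc = int(rng.integers(0, 6))
        w = tuple(sorted(int(x) for x in rng.choice(np.arange(1, L), nw, replace=False)))
        c = tuple(sorted(int(x) for x in rng.choice(np.arange(1, L), nc, replace=False)))
        mols.append(Molecule(ds_len=L, watson_nicks=w, crick_nicks=c))
    return mols


# --------------------------------------------------------------------------
# independent brute-force oracles
# --------------------------------------------------------------------------


def oracle_dsp(mol: Molecule, vicinity=5, lo=30, hi=1000):
    """Explicit enumeration of vicinity pairs, splits and strand runs."""
    pairs = []
    used = set()
    for w in mol.watson_nicks:
        cands = [
            (abs(w - c), j, c)
            for j, c in enumerate(mol.crick_nicks)
            if j not in used and abs(w - c) <= vicinity
        ]
        if cands:
            d, j, c = min(cands)
            used.add(j)
            pairs.append((w, c))
    splits = sorted({w for w, _ in pairs})
    paired_c = {c for _, c in pairs}
    bounds = [0] + splits + [mol.ds_len]
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if b <= a:
            continue
        w_in = [p for p in mol.watson_nicks if a < p < b and p not in splits]
        c_in = [p for p in mol.crick_nicks if a < p < b and p not in paired_c]
        if (not w_in or not c_in) and lo <= b - a <= hi:
            out.append(b - a)
    return sorted(out)


def oracle_ssp(mol: Molecule, stagger=3, hi=1000):
    out = []
    for nicks in (mol.watson_nicks, mol.crick_nicks):
        bounds = [0, *nicks, mol.ds_len]
        for a, b in zip(bounds, bounds[1:]):
            length = b - a + (stagger if nicks else 0)
            if length <= hi:
                out.append(length)
    return sorted(out)


class TestReadoutRules:
    def test_unnicked_molecule(self):
        mol = Molecule(ds_len=166)
        dsp = dsp_readout([mol], EXACT_MODEL, seed=0)
        ssp = ssp_readout([mol], EXACT_MODEL, seed=0)
        assert dsp.counts == {166: 1}
        assert ssp.counts == {166: 2}

    def test_single_nick_keeps_duplex(self):
        """One nicked strand: the intact sister strand carries the duplex."""
        mol = Molecule(ds_len=166, watson_nicks=(83,))
        dsp = dsp_readout([mol], EXACT_MODEL, seed=0)
        assert dsp.counts == {166: 1}

    def test_opposing_nicks_in_vicinity_split(self):
        mol = Molecule(ds_len=166, watson_nicks=(80,), crick_nicks=(82,))
        dsp = dsp_readout([mol], EXACT_MODEL, seed=0)
        assert dsp.counts == {80: 1, 86: 1}

    def test_nicks_on_both_strands_far_apart_lose_the_molecule(self):
        mol = Molecule(ds_len=166, watson_nicks=(50,), crick_nicks=(120,))
        dsp = dsp_readout([mol], EXACT_MODEL, seed=0)
        assert dsp.total == 0

    def test_ssp_piece_count_is_n_plus_one_per_strand(self):
        mol = Molecule(ds_len=166, watson_nicks=(40, 90), crick_nicks=(70,))
        pieces = ssp_pieces(mol, EXACT_MODEL)
        assert len(pieces) == 2 + 3  # (n_w + 1) + (n_c + 1)

    def test_short_ssp_piece_dropped_by_detection_limit(self):
        mol = Molecule(ds_len=166, watson_nicks=(20,))
        ssp = ssp_readout([mol], replace(EXACT_MODEL, ssp_min_len=25, ssp_reliable=25),
                          seed=0)
        assert 23 not in ssp.counts  # 20 + stagger < 25 nt

    def test_conservation_of_duplex_length(self):
        rng = np.random.default_rng(5)
        for mol in random_molecules(200, rng):
            segs = dsp_segments(mol, EXACT_MODEL)
            assert sum(l for l, _ in segs) == mol.ds_len

    def test_readouts_match_brute_force_oracles(self):
        """DSP and SSP rules agree with explicit enumeration on 1,000
        seeded random molecules."""
        rng = np.random.default_rng(99)
        mols = random_molecules(1000, rng)
        got_d = dsp_readout(mols, EXACT_MODEL, seed=1)
        got_s = ssp_readout(mols, EXACT_MODEL, seed=1)
        exp_d: dict[int, int] = {}
        exp_s: dict[int, int] = {}
        for mol in mols:
            for l in oracle_dsp(mol):
                exp_d[l] = exp_d.get(l, 0) + 1
            for l in oracle_ssp(mol):
                exp_s[l] = exp_s.get(l, 0) + 1
        assert got_d.counts == exp_d
        assert got_s.counts == exp_s

    def test_fast_path_equals_molecule_path(self):
        """The vectorized MoleculeSet readout agrees with the per-molecule
        path on a simulated batch (deterministic rules)."""
        params = replace(get_preset("healthy-7"), jitter_sd=0.0)
        mols = simulate_molecules(params, 3000, 7)
        as_list = list(mols)
        fast_d = dsp_readout(mols, EXACT_MODEL, seed=0)
        slow_d = dsp_readout(as_list, EXACT_MODEL, seed=0)
        assert fast_d.counts == slow_d.counts
        fast_s = ssp_readout(mols, EXACT_MODEL, seed=0)
        slow_s = ssp_readout(as_list, EXACT_MODEL, seed=0)
        assert fast_s.counts == slow_s.counts


class TestNickFreeLimit:
    def test_dsp_one_ssp_two_fragments_per_molecule(self):
        params = nick_free_params()
        mols = simulate_molecules(params, 5000, 11)
        dsp = dsp_readout(mols, EXACT_MODEL, seed=0)
        ssp = ssp_readout(mols, EXACT_MODEL, seed=0)
        assert dsp.total == len(mols)
        assert ssp.total == 2 * len(mols)

    def test_histograms_coincide_up_to_stagger(self):
        """Without nicks the two readouts measure the same molecules: the
        single-strand histogram is twice the duplex one, shifted by the
        fixed stagger for cut-terminated (trimmed) classes and unshifted
        for native-ended ones."""
        base = nick_free_params()
        w = dict(zip(CLASSES, base.weights))
        for trimmed in (False, True):
            keep = ("SUBNUC",) if trimmed else ("CHROMATOSOME", "CORE", "DINUC", "TRINUC")
            weights = {c: (1.0 if c in keep else 0.0) for c in CLASSES}
            total = sum(weights.values())
            params = replace(
                base, weights=tuple(weights[c] / total for c in CLASSES)
            )
            mols = simulate_molecules(params, 4000, 11)
            dsp = dsp_readout(mols, EXACT_MODEL, seed=0)
            ssp = ssp_readout(mols, EXACT_MODEL, seed=0)
            shift = EXACT_MODEL.stagger if trimmed else 0
            assert ssp.counts == {l + shift: 2 * c for l, c in dsp.counts.items()}

    def test_zero_nicks_everywhere(self):
        mols = simulate_molecules(nick_free_params(), 2000, 3)
        assert int(mols.n_nicks.sum()) == 0


class TestSimulateMolecules:
    def test_maf_zero_yields_no_malignant(self):
        mols = simulate_molecules(get_preset("healthy-7"), 5000, 2)
        assert not (mols.source == 1).any()

    def test_maf_mixture_weight(self):
        params = malignant_mixture(get_preset("healthy-7"), 40.0)
        mols = simulate_molecules(params, 20000, 2)
        assert (mols.source == 1).mean() == pytest.approx(0.4, abs=0.02)

    def test_maf_coupling_is_nested(self):
        """Raising MAF at a fixed seed only converts molecules, never
        reshuffles the rest (common random numbers)."""
        base = get_preset("healthy-7")
        lo = simulate_molecules(malignant_mixture(base, 10.0), 4000, 5)
        hi = simulate_molecules(malignant_mixture(base, 30.0), 4000, 5)
        assert ((lo.source == 1) & (hi.source == 0)).sum() == 0
        same = (lo.source == hi.source)
        assert (lo.ds_len[same] == hi.ds_len[same]).all()

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(weights=(0.5, 0.5, 0.5, 0, 0, 0))

    def test_out_of_range_maf_rejected(self):
        with pytest.raises(ValueError):
            malignant_mixture(get_preset("healthy-7"), 101.0)

    def test_nicked_fraction_of_mono_family(self):
        """Mono-nucleosome-family molecules are almost always nicked
        (97–98%), the hallmark of continuous nuclease attack."""
        mols = simulate_molecules(get_preset("healthy-7"), 100_000, 1)
        mono = np.isin(mols.origin, [0, 1, 2])
        nicked = (mols.n_nicks[mono] > 0).mean()
        assert 0.97 <= nicked <= 0.98

    def test_nick_positions_strictly_inside(self):
        mols = simulate_molecules(get_preset("healthy-7"), 2000, 4)
        for mol in list(mols)[:200]:
            assert all(0 < p < mol.ds_len for p in mol.watson_nicks)
            assert all(0 < p < mol.ds_len for p in mol.crick_nicks)


class TestCohorts:
    def test_same_seed_is_identical(self):
        a = simulate_cohort("healthy-7", 2, 5000, seed=1)
        b = simulate_cohort("healthy-7", 2, 5000, seed=1)
        for ra, rb in zip(a, b):
            assert ra.dsp.counts == rb.dsp.counts
            assert ra.ssp.counts == rb.ssp.counts
            assert ra.qpcr.concentrations == rb.qpcr.concentrations

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="unknown preset"):
            simulate_cohort("healthy-8", 1, 100, seed=1)

    def test_crc_metastatic_requires_maf(self):
        with pytest.raises(ValueError, match="maf"):
            get_preset("crc-metastatic")

    def test_healthy_profiles_superimpose(self):
        """Simulated healthy DSP profiles are nearly identical across
        individuals (pairwise L1 distance < 0.02).  Sequenced deeply enough
        that sampling noise does not mask the biological homogeneity."""
        cohort = simulate_cohort("healthy-7", 3, 1_500_000, seed=1, readouts=("dsp",))
        profiles = [build_profile(s.dsp, (30, 440)) for s in cohort]
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                l1 = np.abs(profiles[i].freqs - profiles[j].freqs).sum()
                assert l1 < 0.02

    def test_high_mw_visible_to_qpcr_not_wgs(self):
        params = replace(
            get_preset("healthy-7"),
            weights=tuple(1.0 if c == "HIGH_MW" else 0.0 for c in CLASSES),
            jitter_sd=0.0,
        )
        mols = simulate_molecules(params, 500, 9)
        assert dsp_readout(mols, seed=0).total == 0
        assert ssp_readout(mols, seed=0).total == 0
        from cffrag.qpcr import insilico_qpcr

        assert insilico_qpcr(mols).concentrations[320] > 0


class TestStaggerObservable:
    def test_ssp_subpeaks_sit_3nt_above_dsp(self):
        """The 3' stagger makes SSP sub-peaks sit ~3 nt above DSP's."""
        cohort = simulate_cohort("healthy-7", 1, 300_000, seed=1,
                                 readouts=("dsp", "ssp"))
        dsp = build_profile(cohort[0].dsp, (30, 440))
        ssp = build_profile(cohort[0].ssp, (30, 440))
        rep_d = detect_subpeaks(dsp, (90, 145))
        rep_s = detect_subpeaks(ssp, (90, 145))
        assert len(rep_d.positions) >= 3
        assert len(rep_s.positions) >= 3
        assert periodicity(rep_d) in (10, 11)
        assert stagger_offset(rep_s, rep_d) == 3


class TestModelValidation:
    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            NucleosomeModel(peel_discard_prob=1.5)

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            NucleosomeModel(core_len=0)
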