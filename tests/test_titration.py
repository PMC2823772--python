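import numpy as np
import pytest

from pbsalink.constants import KT_LN10
from pbsalink.model_io import Atom, ParameterizedStructure
from pbsalink.pb import GridSpec
from pbsalink import synth
from pbsalink.titration import (
    TitratableSite,
    define_sites,
    henderson_hasselbalch,
    intrinsic_pka,
    site_interaction_matrix,
    titrate,
    verify_ionization_states,
)


def _site(pka, acid=True, idx=0, name="S"):
    return TitratableSite(id=f"{name}{idx}", atom_index=idx, model_pka=pka,
                          is_acid=acid, intrinsic_pka=pka)


def _peptide(with_gdp=False):
    atoms = [
        Atom(1, "CA", "ALA", 1, "A", [0, 0, 0], 0.0, 0.1, 2.0, 2.0),
        Atom(2, "OD2", "ASP", 2, "A", [3, 0, 0], 0.0, 0.12, 1.7, 1.6),
        Atom(3, "CB", "ASP", 2, "A", [4, 1, 0], 0.0, 0.1, 2.0, 2.0),
    ]
    if with_gdp:
        atoms += [
            Atom(4, "PB", "GDP", 9, "L", [8, 0, 0], -1.1, 0.58, 2.15, 2.1),
            Atom(5, "O2B", "GDP", 9, "L", [9.5, 0.5, 0], -0.95, 0.12, 1.7, 1.6),
        ]
    return ParameterizedStructure(atoms)


class TestDefineSites:
    def test_single_asp_found(self):
        sites = define_sites(_peptide())
        assert len(sites) == 1
        assert sites[0].model_pka == 4.0
        assert sites[0].is_acid

    def test_phosphate_flag_adds_o2b_at_6_4(self):
        sites = define_sites(_peptide(with_gdp=True), include_phosphate_o2b=True)
        ids = {s.id for s in sites}
        assert any("O2B" in i for i in ids)
        o2b = next(s for s in sites if "O2B" in s.id)
        assert o2b.model_pka == pytest.approx(6.4)
        assert o2b.is_acid

    def test_flag_off_omits_o2b(self):
        sites = define_sites(_peptide(with_gdp=True), include_phosphate_o2b=False)
        assert not any("O2B" in s.id for s in sites)

    def test_missing_titratable_atom_names_site(self):
        atoms = [Atom(1, "CB", "ASP", 7, "A", [0, 0, 0], 0.0, 0.1, 2.0, 2.0)]
        with pytest.raises(ValueError, match="ASP7"):
            define_sites(ParameterizedStructure(atoms))


class TestExactTitration:
    def test_single_site_is_henderson_hasselbalch(self):
        site = _site(6.0)
        res = titrate([site], ph_range=(2, 10), n_ph=33)
        expected = henderson_hasselbalch(res.ph_grid, 6.0)
        np.testing.assert_allclose(res.mean_protonation[:, 0], expected,
                                   atol=1e-12)
        assert res.pka_half[0] == pytest.approx(6.0, abs=1e-9)

    def test_two_coupled_acids_match_4state_oracle(self):
        sites, W, curve_fn = synth.two_site_titration_fixture(5.0, 6.0, 1.36)
        res = titrate(sites, W, ph_range=(0, 14), n_ph=29)
        for k, ph in enumerate(res.ph_grid):
            np.testing.assert_allclose(res.mean_protonation[k], curve_fn(ph),
                                       atol=1e-10)

    def test_identical_sites_with_large_coupling_split_symmetrically(self):
        """Two identical acids coupled by w (between their charged,
        deprotonated forms) titrate in two waves symmetric about
        pKa + w / (2 ln10 kT)."""
        pka, w = 6.0, 4.0
        sites, W, _ = synth.two_site_titration_fixture(pka, pka, w)
        res = titrate(sites, W, ph_range=(0, 14), n_ph=57)
        total = res.mean_protonation.sum(axis=1)  # 2 -> 0 protons
        ph_hi = np.interp(-0.5, -total, res.ph_grid)  # 0.5 protons left
        ph_lo = np.interp(-1.5, -total, res.ph_grid)  # 1.5 protons left
        center = pka + w / (2 * KT_LN10)
        assert (ph_lo + ph_hi) / 2 == pytest.approx(center, abs=0.05)
        assert ph_hi - ph_lo > 1.0  # genuinely split

    def test_zero_coupling_factorizes(self, rng):
        sites = [_site(4.0, True, 0), _site(7.5, False, 1), _site(10.0, True, 2)]
        res = titrate(sites, np.zeros((3, 3)), ph_range=(0, 14), n_ph=29)
        for j, s in enumerate(sites):
            np.testing.assert_allclose(
                res.mean_protonation[:, j],
                henderson_hasselbalch(res.ph_grid, s.model_pka),
                atol=1e-12,
            )

    def test_relabeling_invariance(self):
        sites = [_site(5.0, True, 0), _site(8.0, False, 1)]
        W = np.array([[0.0, 0.7], [0.7, 0.0]])
        res = titrate(sites, W, n_ph=15)
        res_swapped = titrate(sites[::-1], W[::-1][:, ::-1], n_ph=15)
        np.testing.assert_allclose(res.mean_protonation[:, 0],
                                   res_swapped.mean_protonation[:, 1],
                                   atol=1e-12)

    def test_microstate_probabilities_sum_to_one(self):
        from pbsalink.titration import _microstate_energies
        from pbsalink.constants import KT

        sites = [_site(5.0, True, 0), _site(8.0, False, 1), _site(7.0, True, 2)]
        W = np.full((3, 3), 0.4)
        np.fill_diagonal(W, 0.0)
        states = ((np.arange(8)[:, None] >> np.arange(3)[None, :]) & 1).astype(float)
        e = _microstate_energies(sites, W, states, 7.0)
        p = np.exp(-(e - e.min()) / KT)
        p /= p.sum()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_limited_to_20_sites(self):
        sites = [_site(7.0, True, i) for i in range(21)]
        with pytest.raises(ValueError, match="monte-carlo"):
            titrate(sites, np.zeros((21, 21)))


class TestMonteCarloTitration:
    def test_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            titrate([_site(7.0)], method="monte-carlo")

    def test_matches_exact_on_10_site_fixture(self):
        """Seeded Metropolis sampling reproduces the exact pKa-half of a
        10-site randomly coupled fixture within 0.05 pH units."""
        rng = np.random.default_rng(42)
        n = 10
        sites = [
            TitratableSite(id=f"S{i}", atom_index=i,
                           model_pka=float(rng.uniform(3, 11)),
                           is_acid=bool(rng.random() < 0.5))
            for i in range(n)
        ]
        for s in sites:
            s.intrinsic_pka = s.model_pka
        W = np.abs(rng.normal(0, 0.8, (n, n))) * 0.8
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        exact = titrate(sites, W, ph_range=(0, 14), n_ph=29)
        mc = titrate(sites, W, ph_range=(0, 14), n_ph=29,
                     method="monte-carlo", seed=7)
        assert mc.mc_seed == 7
        dev = np.nanmax(np.abs(exact.pka_half - mc.pka_half))
        assert dev <= 0.05

    def test_reproducible_under_seed(self):
        sites, W, _ = synth.two_site_titration_fixture(5.0, 7.0, 1.0)
        a = titrate(sites, W, n_ph=9, method="monte-carlo", seed=3)
        b = titrate(sites, W, n_ph=9, method="monte-carlo", seed=3)
        np.testing.assert_array_equal(a.mean_protonation, b.mean_protonation)


class TestIntrinsicPka:
    LADDER = [GridSpec((0, 0, 0), 25, 1.0), GridSpec((0, 0, 0), 25, 0.5)]

    def test_model_compound_alone_recovers_model_pka(self):
        """A 'protein' consisting of only the model compound has zero
        shift: the two environments are identical by construction."""
        atoms = [Atom(1, "OD2", "ASP", 1, "A", [0, 0, 0], 0.0, 0.12, 1.7, 1.6)]
        s = ParameterizedStructure(atoms)
        site = define_sites(s)[0]
        pka = intrinsic_pka(site, s, self.LADDER)
        assert pka == pytest.approx(4.0, abs=1e-6)

    def test_burial_by_neutral_occluders_raises_acid_pka(self):
        """Pure desolvation (uncharged occluders) penalizes the charged
        form: an acid's intrinsic pKa shifts upward."""
        occluders = [
            Atom(i + 2, "CG", "OCC", 2 + i, "A", p, 0.0, 0.1, 2.0, 2.2)
            for i, p in enumerate(
                3.2 * np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                                [0, 0, 1], [0, 0, -1], [1, 1, 1], [-1, -1, -1]])
                / np.array([1, 1, 1, 1, 1, 1, np.sqrt(3), np.sqrt(3)])[:, None]
            )
        ]
        atoms = [Atom(1, "OD2", "ASP", 1, "A", [0, 0, 0], 0.0, 0.12, 1.7, 1.6)]
        s = ParameterizedStructure(atoms + occluders)
        site = define_sites(s)[0]
        pka = intrinsic_pka(site, s, self.LADDER)
        assert pka > 4.0 + 0.2

    def test_nearby_positive_background_lowers_acid_pka(self):
        """A fixed +1 e background charge 3 Å from an acid favours its
        ionized form, lowering the intrinsic pKa — the salt-bridge effect
        that keeps a nucleotide phosphate fully ionized at pH 7."""
        atoms = [
            Atom(1, "O2B", "GDP", 1, "L", [0, 0, 0], -0.95, 0.12, 1.7, 1.6),
            Atom(2, "PB", "GDP", 1, "L", [1.6, 0, 0], -1.1, 0.58, 2.15, 2.1),
            Atom(3, "NZ", "LYS", 30, "A", [-3.0, 0, 0], 1.0, 0.2, 1.85, 1.8),
        ]
        s = ParameterizedStructure(atoms)
        sites = define_sites(s, include_phosphate_o2b=True)
        o2b = next(x for x in sites if "O2B" in x.id)
        # background = the bare salt-bridge partner only
        bg = np.array([0.0, 0.0, 1.0])
        pka = intrinsic_pka(o2b, s, self.LADDER, background_charges=bg)
        assert pka < 6.4 - 0.3  # solvent-screened but clearly downward


class TestSiteInteractions:
    LADDER = [GridSpec((10, 0, 0), 33, 1.5)]

    def _two_site_structure(self, d):
        atoms = [
            Atom(1, "OD2", "ASP", 1, "A", [0, 0, 0], 0.0, 0.12, 1.7, 1.6),
            Atom(2, "OE2", "GLU", 2, "A", [d, 0, 0], 0.0, 0.12, 1.7, 1.6),
        ]
        return ParameterizedStructure(atoms)

    def test_distant_sites_decouple(self):
        s = ParameterizedStructure([
            Atom(1, "OD2", "ASP", 1, "A", [-45, 0, 0], 0.0, 0.12, 1.7, 1.6),
            Atom(2, "OE2", "GLU", 2, "A", [55, 0, 0], 0.0, 0.12, 1.7, 1.6),
        ])
        sites = define_sites(s)
        specs = [GridSpec((5, 0, 0), 61, 2.0)]
        W = site_interaction_matrix(sites, s, specs)
        assert abs(W[0, 1]) < 0.05

    def test_symmetric_within_tolerance(self):
        s = self._two_site_structure(6.0)
        sites = define_sites(s)
        specs = [GridSpec((3, 0, 0), 33, 1.0)]
        from pbsalink.titration import _site_potential
        import pbsalink.pb as pbmod

        xyz = s.coords
        phi0, _ = _site_potential(sites[0], s, specs, 20.0, 80.0, 150.0, 2.0, 1e-7)
        phi1, _ = _site_potential(sites[1], s, specs, 20.0, 80.0, 150.0, 2.0, 1e-7)
        w01 = sites[1].delta_charge * float(phi0.interpolator()(xyz[1][None])[0])
        w10 = sites[0].delta_charge * float(phi1.interpolator()(xyz[0][None])[0])
        assert w01 == pytest.approx(w10, rel=0.02)

    def test_like_charges_repel(self):
        s = self._two_site_structure(5.0)
        sites = define_sites(s)
        specs = [GridSpec((2.5, 0, 0), 33, 1.0)]
        W = site_interaction_matrix(sites, s, specs)
        assert W[0, 1] > 0.0
        assert W[0, 0] == 0.0 and W[1, 1] == 0.0


class TestVerifyIonizationStates:
    def test_unshifted_sites_not_flagged(self):
        sites = [_site(4.0, True, 0), _site(10.4, False, 1)]
        res = titrate(sites, np.zeros((2, 2)))
        report = verify_ionization_states(sites, res)
        assert not any(r["flagged"] for r in report)

    def test_low_pka_phosphate_reported_ionized(self):
        """An O2B-like acid whose computed pKa-half lies far below 7 is
        reported deprotonated (charged), consistent with a fully ionized
        triphosphate-like charge state."""
        o2b = TitratableSite(id="GDP/O2B", atom_index=0, model_pka=6.4,
                             is_acid=True, intrinsic_pka=1.7)
        res = titrate([o2b], ph_range=(-2, 14))
        report = verify_ionization_states([o2b], res)
        assert report[0]["charged"]
        assert report[0]["pka_half"] == pytest.approx(1.7, abs=1e-6)

    def test_strongly_shifted_base_flagged(self):
        his = TitratableSite(id="HIS1", atom_index=0, model_pka=6.3,
                             is_acid=False, intrinsic_pka=9.5)
        res = titrate([his], ph_range=(0, 14))
        report = verify_ionization_states([his], res)
        assert report[0]["flagged"]


def test_kt_ln10_converts_ph_to_energy():
    # 1 pH unit at 300 K is about 1.37 kcal/mol
    assert KT_LN10 == pytest.approx(1.3726, abs=1e-3)
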