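"""Binding histograms, Gaussian peak fits, and affinity estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopkmc.binding_model import (
    BindingEvent,
    PeakFitError,
    binding_histogram,
    center_histogram,
    fit_gaussian_peak,
    overall_kd,
    site_affinity,
    theta_within_peak,
)


def _gauss_hist(length, mu, w, amp=100.0):
    x = np.arange(1, length + 1, dtype=float)
    return amp * np.exp(-(((x - mu) / w) ** 2))


class TestHistograms:
    def test_single_protein_increments_covered_bp_by_one(self):
        ev = BindingEvent("d1", ((10, 20),))
        hist = binding_histogram([ev], 50)
        assert np.all(hist[9:20] == 1.0)
        assert hist.sum() == pytest.approx(11.0)

    def test_split_contact_weights_each_region_by_half(self):
        ev = BindingEvent("d1", ((5, 10), (30, 35)))
        hist = binding_histogram([ev], 50)
        assert np.all(hist[4:10] == 0.5)
        assert np.all(hist[29:35] == 0.5)

    def test_no_events_gives_zero_vector(self):
        assert binding_histogram([], 25).sum() == 0.0

    def test_out_of_range_contact_names_event(self):
        ev = BindingEvent("weird", ((90, 120),))
        with pytest.raises(ValueError, match="weird"):
            binding_histogram([ev], 100)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_center_histogram_mass_equals_protein_count(self, seed):
        """1/k weighting conserves one unit of mass per protein, exactly."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        events = []
        for i in range(n):
            k = int(rng.integers(1, 4))
            contacts = []
            for _ in range(k):
                lo = int(rng.integers(1, 180))
                contacts.append((lo, lo + int(rng.integers(0, 20))))
            events.append(BindingEvent(f"d{i}", tuple(contacts)))
        hist = center_histogram(events, 200)
        assert hist.sum() == pytest.approx(n, abs=1e-9)

    def test_event_weights_sum_to_one(self):
        ev = BindingEvent("d1", ((1, 5), (10, 12), (40, 44)))
        assert ev.weight * len(ev.contacts) == pytest.approx(1.0)


class TestPeakFit:
    def test_noiseless_full_site_peak_recovered(self):
        """Synthesized peak at the full-site parameters (mu = 151.3 bp,
        w = 51.46 bp) is recovered to better than 0.1%."""
        hist = _gauss_hist(600, 151.3, 51.46)
        fit = fit_gaussian_peak(hist, (20, 400))
        assert fit.mu == pytest.approx(151.3, rel=1e-3)
        assert fit.w == pytest.approx(51.46, rel=1e-3)

    def test_symmetric_histogram_centers_mu_at_midpoint(self):
        hist = np.zeros(21)
        hist[[5, 7, 9, 11, 13, 15]] = [1.0, 3.0, 6.0, 6.0, 3.0, 1.0]
        fit = fit_gaussian_peak(hist, (1, 21))
        assert fit.mu == pytest.approx(11.0, abs=1e-6)  # bp 11 by symmetry

    def test_flat_window_raises(self):
        with pytest.raises(PeakFitError, match="flat"):
            fit_gaussian_peak(np.ones(40), (1, 40))

    def test_sparse_window_raises(self):
        hist = np.zeros(40)
        hist[10] = 5.0
        with pytest.raises(PeakFitError, match="fewer than 5"):
            fit_gaussian_peak(hist, (1, 40))

    def test_translation_equivariance(self):
        base = _gauss_hist(500, 120.0, 30.0)
        shifted = np.roll(base, 140)
        f0 = fit_gaussian_peak(base, (40, 220))
        f1 = fit_gaussian_peak(shifted, (180, 360))
        assert f1.mu - f0.mu == pytest.approx(140.0, abs=1e-3)
        assert f1.w == pytest.approx(f0.w, abs=1e-3)

    def test_poisson_noise_ci_coverage(self):
        """True mu falls inside the reported 95% CI in >= 90% of replicates."""
        truth = 100.0
        lam = _gauss_hist(220, truth, 25.0, amp=40.0)
        rng = np.random.default_rng(77)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            fit = fit_gaussian_peak(
                rng.poisson(lam).astype(float), (30, 170), counting_noise=True
            )
            hits += fit.mu_ci[0] <= truth <= fit.mu_ci[1]
        assert hits / n_rep >= 0.90


class TestAffinity:
    def test_worked_example_exact(self):
        est = overall_kd(theta=0.5, n_bound=1, protein0=50.0, dna0=2.5)
        assert est.value == pytest.approx(47.5, abs=1e-12)

    def test_saturated_limit_is_zero(self):
        assert overall_kd(1.0, 0.0, 50.0, 2.5).value == 0.0

    def test_invalid_theta_or_depletion(self):
        with pytest.raises(ValueError):
            overall_kd(0.0, 1, 50, 2.5)
        with pytest.raises(ValueError, match="negative"):
            overall_kd(0.5, 30, 50, 2.5)

    def test_site_affinity_worked_example(self):
        est = site_affinity(0.5, 10.0)
        assert est.value == pytest.approx(0.1, abs=1e-12)

    def test_site_affinity_monotone_in_occupancy(self):
        values = [site_affinity(t, 10.0).value for t in np.linspace(0.05, 0.95, 12)]
        assert np.all(np.diff(values) > 0)

    def test_site_affinity_boundaries_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(ValueError):
                site_affinity(bad, 10.0)

    def test_overall_and_site_formulas_agree_on_single_site(self):
        """With one site per molecule (n = Theta), Kd_overall equals
        1/Ka_ss evaluated at the implied free concentration."""
        for theta in (0.1, 0.35, 0.7):
            p0, d0 = 50.0, 2.5
            free = p0 - theta * d0
            kd_overall = overall_kd(theta, theta, p0, d0).value
            kd_site = 1.0 / site_affinity(theta, free).value
            assert kd_overall == pytest.approx(kd_site, rel=1e-12)

    def test_theta_within_peak_counts_molecules_once(self):
        events = [
            BindingEvent("d1", ((95, 105),)),
            BindingEvent("d1", ((98, 102),)),  # same molecule, second protein
            BindingEvent("d2", ((300, 310),)),
        ]
        theta = theta_within_peak(events, mu=100.0, w=20.0, n_molecules=4)
        assert theta == pytest.approx(1 / 4)


class TestTwoSiteRecovery:
    def test_per_site_ka_ratio_recovered_from_synthetic_dataset(self):
        """Two sites generated with a 2:1 affinity ratio: per-site occupancy
        counting plus the site-affinity formula recovers the ratio within a
        bootstrap CI over molecules."""
        from rloopkmc.synthetic_data import BindingSite, GeneratorSpec, synth_binding_dataset

        spec = GeneratorSpec(
            seed=91,
            n_molecules=1500,
            background_rate=0.0,
            position_sigma=30.0,
            sites=(
                BindingSite("strong", 190, 213, 0.10),
                BindingSite("weak", 690, 713, 0.05),
            ),
        )
        events_df, truth = synth_binding_dataset(spec)
        centers = ((events_df.contact_start + events_df.contact_end) / 2).to_numpy()
        mol_idx = events_df.dna_id.str.slice(3).astype(int).to_numpy()
        free = truth["free_protein"]
        half_window = 2 * spec.position_sigma

        def bound_matrix():
            mat = np.zeros((spec.n_molecules, 2), dtype=bool)
            for j, site in enumerate(spec.sites):
                hit = np.abs(centers - site.center) <= half_window
                mat[np.unique(mol_idx[hit]), j] = True
            return mat

        mat = bound_matrix()
        rng = np.random.default_rng(17)
        ratios = []
        for _ in range(400):
            sel = rng.integers(0, spec.n_molecules, spec.n_molecules)
            th = mat[sel].mean(axis=0)
            # the counting window misses the tails symmetrically at both
            # sites, so the affinity ratio is unaffected
            ka = [site_affinity(float(t), free).value for t in th]
            ratios.append(ka[0] / ka[1])
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        assert lo <= 2.0 <= hi
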