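"""Copying-model painting: forward-backward, Viterbi, label collapse."""
import numpy as np
import pytest

from finehap import calibration as cal
from finehap import paint
from finehap.panel import HaplotypePanel
from finehap.simulate import simulate_founders, simulate_mosaic_panel


def random_instance(rng, D, L):
    donors = rng.integers(0, 2, size=(D, L)).astype(np.uint8)
    target = donors[rng.integers(0, D)].copy()
    flips = rng.random(L) < 0.15
    target[flips] ^= 1
    d = rng.uniform(0.001, 0.02, size=L - 1)
    params = paint.CopyingModelParams(rho=float(rng.uniform(5, 100)),
                                      theta=float(rng.uniform(0.01, 0.3)))
    return target, donors, d, params


class TestForwardBackward:
    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(6):
            D = int(rng.integers(2, 5))
            L = int(rng.integers(3, 8))
            target, donors, d, params = random_instance(rng, D, L)
            pm = paint.copying_forward_backward(target, donors, d, params)
            bp, bll = cal.exhaustive_copying_posteriors(target, donors, d, params)
            assert np.abs(pm.posteriors - bp).max() < 1e-10
            assert abs(pm.log_likelihood - bll) < 1e-10 * max(1, abs(bll))

    def test_exact_copy_dominates(self, rng):
        donors = rng.integers(0, 2, size=(3, 5)).astype(np.uint8)
        donors[1] = 1 - donors[0]
        donors[2] = np.roll(1 - donors[0], 2)
        target = donors[0].copy()
        params = paint.CopyingModelParams(rho=10.0, theta=0.01)
        pm = paint.copying_forward_backward(target, donors, np.full(4, 0.01), params)
        assert np.all(pm.argmax_donor() == 0)

    def test_uninformative_theta_gives_uniform_posterior(self, rng):
        target, donors, d, _ = random_instance(rng, 4, 6)
        params = paint.CopyingModelParams(rho=20.0, theta=0.5)
        pm = paint.copying_forward_backward(target, donors, d, params)
        assert np.allclose(pm.posteriors, 0.25, atol=1e-12)

    def test_single_site_closed_form(self):
        target = np.array([1])
        donors = np.array([[1], [0], [1]])
        params = paint.CopyingModelParams(rho=1.0, theta=0.1)
        pm = paint.copying_forward_backward(target, donors, np.empty(0), params)
        expected = np.array([0.9, 0.1, 0.9])
        assert np.allclose(pm.posteriors[0], expected / expected.sum())

    def test_rows_normalized(self, rng):
        target, donors, d, params = random_instance(rng, 4, 7)
        pm = paint.copying_forward_backward(target, donors, d, params)
        assert np.abs(pm.posteriors.sum(axis=1) - 1).max() < 1e-9

    def test_no_underflow_on_long_panels(self, rng):
        L = 20_000
        donors = rng.integers(0, 2, size=(5, L)).astype(np.uint8)
        target = donors[2].copy()
        params = paint.CopyingModelParams(rho=100.0, theta=0.01)
        pm = paint.copying_forward_backward(target, donors,
                                            np.full(L - 1, 1e-4), params)
        assert np.isfinite(pm.log_likelihood)
        assert np.abs(pm.posteriors.sum(axis=1) - 1).max() < 1e-9

    def test_monotone_informativeness(self, rng):
        """For an exactly matching donor, smaller theta never lowers its
        posterior at matched sites."""
        donors = rng.integers(0, 2, size=(3, 8)).astype(np.uint8)
        donors[1] = 1 - donors[0]
        target = donors[0].copy()
        d = np.full(7, 0.01)
        prev = None
        for theta in (0.4, 0.2, 0.1, 0.02):
            pm = paint.copying_forward_backward(
                target, donors, d, paint.CopyingModelParams(rho=10.0, theta=theta))
            cur = pm.posteriors[:, 0]
            if prev is not None:
                assert np.all(cur >= prev - 1e-12)
            prev = cur

    def test_input_validation(self, rng):
        target, donors, d, params = random_instance(rng, 3, 5)
        with pytest.raises(ValueError):
            paint.copying_forward_backward(target[:-1], donors, d, params)
        with pytest.raises(ValueError):
            paint.copying_forward_backward(target, donors[:0], d, params)


class TestViterbi:
    def test_matches_exhaustive_maximization(self, rng):
        checked = 0
        while checked < 5:
            D = int(rng.integers(2, 4))
            L = int(rng.integers(3, 7))
            target, donors, d, params = random_instance(rng, D, L)
            path, ll = paint.viterbi_copying(target, donors, d, params)
            bpath, bll, unique = cal.exhaustive_viterbi(target, donors, d, params)
            assert abs(ll - bll) < 1e-9 * max(1, abs(bll))
            if unique:
                assert np.array_equal(path, bpath)
                checked += 1

    def test_exact_copy_constant_path(self, rng):
        donors = rng.integers(0, 2, size=(4, 6)).astype(np.uint8)
        donors[1:] = 1 - donors[0]
        target = donors[0].copy()
        params = paint.CopyingModelParams(rho=10.0, theta=0.01)
        path, _ = paint.viterbi_copying(target, donors, np.full(5, 0.01), params)
        assert np.all(path == 0)

    def test_no_switch_limit_equals_best_global_donor(self, rng):
        target, donors, d, _ = random_instance(rng, 4, 6)
        params = paint.CopyingModelParams(rho=0.0, theta=0.1)
        path, _ = paint.viterbi_copying(target, donors, d, params)
        assert len(set(path.tolist())) == 1
        match = (donors == target[None, :]).sum(axis=1)
        assert match[path[0]] == match.max()


class TestLabelPath:
    def _painting(self, post):
        post = np.asarray(post, dtype=float)
        return paint.PaintingMatrix(post, np.arange(post.shape[1]), 0.0,
                                    np.ones(post.shape[0]))

    def test_single_label_everywhere(self):
        pm = self._painting([[0.2, 0.3, 0.5]] * 4)
        lp = paint.label_sites_by_tag_haplotype(pm, ["A", "A", "A"])
        assert np.all(lp.labels == "A")
        assert np.allclose(lp.label_posteriors, 1.0)

    def test_label_sum_beats_single_donor(self):
        pm = self._painting([[0.3, 0.3, 0.4]])
        lp = paint.label_sites_by_tag_haplotype(pm, ["A", "A", "B"])
        assert lp.labels[0] == "A"
        assert lp.label_posteriors[0].tolist() == pytest.approx([0.6, 0.4])

    def test_grouped_recomputation(self, rng):
        post = rng.dirichlet(np.ones(6), size=10)
        labels = np.array(["x", "y", "x", "z", "y", "x"])
        pm = self._painting(post)
        lp = paint.label_sites_by_tag_haplotype(pm, labels)
        for g, name in enumerate(lp.label_names):
            expected = post[:, labels == name].sum(axis=1)
            assert np.allclose(lp.label_posteriors[:, g], expected)

    def test_unlabeled_donor_rejected(self):
        pm = self._painting([[0.5, 0.5]])
        with pytest.raises(ValueError):
            paint.label_sites_by_tag_haplotype(pm, ["A", ""])

    def test_switch_points(self):
        lp = paint.LabelPath(labels=np.array(["A", "A", "B", "B"]),
                             label_names=np.array(["A", "B"]),
                             label_posteriors=np.eye(2)[[0, 0, 1, 1]])
        recs = paint.detect_switch_points(lp, positions=[100, 200, 300, 400])
        assert len(recs) == 1
        assert recs[0]["interval_bp"] == (200, 300)
        assert (recs[0]["from_label"], recs[0]["to_label"]) == ("A", "B")

    def test_constant_path_no_switches(self):
        lp = paint.LabelPath(labels=np.array(["A"] * 5),
                             label_names=np.array(["A"]),
                             label_posteriors=np.ones((5, 1)))
        assert paint.detect_switch_points(lp, positions=range(5)) == []


class TestSelectHomozygotes:
    def test_phased_panel_selection(self):
        alleles = np.array([[0, 0, 0], [0, 0, 0],   # hom 000
                            [1, 1, 1], [1, 1, 1],   # hom 111
                            [0, 0, 0], [1, 1, 1]])  # het
        panel = HaplotypePanel(alleles, [10, 20, 30], ["a", "b", "c"])
        assert paint.select_homozygotes(panel, [0, 1, 2], "000").tolist() == [0]
        assert paint.select_homozygotes(panel, [0, 1, 2], "111").tolist() == [1]

    def test_genotype_matrix_selection(self):
        G = np.array([[0, 0], [2, 2], [1, 1], [0, 2]])
        assert paint.select_homozygotes(G, [0, 1], "00").tolist() == [0]
        assert paint.select_homozygotes(G, [0, 1], "11").tolist() == [1]
        assert paint.select_homozygotes(G, [0, 1], "01").tolist() == [3]

    def test_matches_truth_on_simulated_panel(self, cohort):
        idx = paint.select_homozygotes(cohort.panel,
                                       cohort.panel.tag_site_indices, "01101")
        labels = cohort.panel.tag_labels()
        truth = np.flatnonzero((labels[0::2] == "01101") & (labels[1::2] == "01101"))
        assert np.array_equal(idx, truth)


class TestPaintingQuality:
    def test_uninformative_equals_one_over_D(self, rng):
        target, donors, d, _ = random_instance(rng, 5, 6)
        pm = paint.copying_forward_backward(
            target, donors, d, paint.CopyingModelParams(rho=10.0, theta=0.5))
        q = paint.painting_quality([pm])
        assert q["median"] == pytest.approx(0.2, abs=1e-12)

    def test_summary_equals_recomputation(self, rng):
        pms = []
        for _ in range(4):
            target, donors, d, params = random_instance(rng, 3, 6)
            pms.append(paint.copying_forward_backward(target, donors, d, params))
        q = paint.painting_quality(pms)
        med = [float(np.median(p.posteriors.max(axis=1))) for p in pms]
        assert q["median"] == pytest.approx(np.median(med))
        assert q["min"] == pytest.approx(min(med))


class TestMosaicRecovery:
    def test_argmax_donor_recovers_truth(self, rng):
        """Painting mosaics of well-separated founders recovers the true
        donor at >= 95% of sites (mutation rate 0.001)."""
        founders = simulate_founders(8, 300, 0.5, rng)
        d = np.full(299, 2e-4)
        alleles, paths, _ = simulate_mosaic_panel(founders, d, 30,
                                                  switch_scale=10.0,
                                                  mutation_rate=0.001, seed=9)
        params = paint.CopyingModelParams(rho=10.0, theta=0.01)
        hits = total = 0
        for i in range(30):
            pm = paint.copying_forward_backward(alleles[i], founders, d, params)
            hits += int((pm.argmax_donor() == paths[i]).sum())
            total += 300
        assert hits / total >= 0.95

    def test_switch_detection_within_identifiability_tract(self, rng):
        """Every true switch is detected within one inter-site interval of
        the tract where the old and new donors are identical (inside that
        tract the switch position carries no information)."""
        founders = simulate_founders(6, 200, 0.5, rng)
        d = np.full(199, 5e-4)
        alleles, paths, _ = simulate_mosaic_panel(founders, d, 25,
                                                  switch_scale=8.0,
                                                  mutation_rate=0.0, seed=10)
        params = paint.CopyingModelParams(rho=8.0, theta=0.005)
        found_near = missed = 0
        for i in range(25):
            pm = paint.copying_forward_backward(alleles[i], founders, d, params)
            lp = paint.label_sites_by_tag_haplotype(
                pm, [str(k) for k in range(6)])
            detected = set(lp.switch_sites().tolist())
            true_switches = np.flatnonzero(paths[i][1:] != paths[i][:-1]) + 1
            for s in true_switches:
                old, new = paths[i][s - 1], paths[i][s]
                lo = s
                while lo > 1 and founders[old, lo - 1] == founders[new, lo - 1]:
                    lo -= 1
                hi = s
                while (hi < 199
                       and founders[old, hi] == founders[new, hi]):
                    hi += 1
                if detected & set(range(lo - 1, hi + 2)):
                    found_near += 1
                else:
                    missed += 1
        assert found_near / max(found_near + missed, 1) >= 0.95
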