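"""Differential HDX, bimodal deconvolution, per-residue maps."""

import numpy as np
import pandas as pd
import pytest

from ringfit import synthgen
from ringfit.hdx import (
    differential_hdx,
    fit_bimodal,
    max_exchangeable,
    modes_unidentifiable,
    uptake_summary,
)

TIMEPOINTS = [0.0, 0.008, 0.05, 0.5, 3.0, 30.0]


def uptake_table(peptides, state):
    """Build a long-format uptake table from {pid: (start, end, uptakes)}."""
    rows = []
    for pid, (start, end, uptakes) in peptides.items():
        for t, u in zip(TIMEPOINTS, uptakes):
            rows.append(dict(peptide_id=pid, start=start, end=end,
                             sequence="A" * (end - start + 1), state=state,
                             timepoint_h=t, uptake_Da=u, sem=0.05))
    return pd.DataFrame(rows)


class TestMaxExchangeable:
    def test_counts_amides(self):
        # 10 residues, one P after the first: 10 - 1 - 1 = 8
        assert max_exchangeable("ACDEFPGHIK") == 8

    def test_leading_proline_not_double_counted(self):
        assert max_exchangeable("PAAAA") == 4


class TestDifferentialHdx:
    def test_identical_states_no_change(self):
        pep = {"p1": (1, 10, [0, 1, 2, 3, 4, 5])}
        diff, skipped = differential_hdx(uptake_table(pep, "apo"),
                                         uptake_table(pep, "bound"))
        assert skipped == []
        assert (diff["delta_Da"] == 0).all()
        assert (diff["classification"] == "no-change").all()

    def test_uniform_protection_classified(self):
        apo = {"p1": (1, 10, [0, 1, 2, 3, 4, 5])}
        bound = {"p1": (1, 10, [0, 1, 0.8, 1.8, 2.8, 3.8])}  # -1.2 Da at 4 tps
        diff, _ = differential_hdx(uptake_table(apo, "apo"),
                                   uptake_table(bound, "bound"),
                                   threshold_Da=0.5, min_timepoints=2)
        assert (diff["classification"] == "protected").all()

    def test_deprotection_classified(self):
        apo = {"p1": (1, 10, [0, 1, 1, 1, 1, 1])}
        bound = {"p1": (1, 10, [0, 1, 2, 2, 2, 2])}
        diff, _ = differential_hdx(uptake_table(apo, "apo"),
                                   uptake_table(bound, "bound"))
        assert (diff["classification"] == "deprotected").all()

    def test_unmatched_peptides_reported_and_skipped(self):
        apo = uptake_table({"p1": (1, 10, [0, 1, 2, 3, 4, 5]),
                            "only_apo": (20, 30, [0, 1, 2, 3, 4, 5])}, "apo")
        bound = uptake_table({"p1": (1, 10, [0, 1, 2, 3, 4, 5])}, "bound")
        diff, skipped = differential_hdx(apo, bound)
        assert skipped == ["only_apo"]
        assert set(diff["peptide_id"]) == {"p1"}

    def test_strongly_protected_tail_peptide_ranks_first(self):
        """A disordered-tail peptide given strong bound-state protection has
        the largest summed delta in a mixed peptide set."""
        base = [0.0, 0.5, 1.5, 3.0, 4.5, 6.0]
        apo = {
            "p_331_355": (331, 355, base),
            "p_383_413": (383, 413, [u * 1.6 for u in base]),
            "p_120_140": (120, 140, base),
        }
        bound = {
            "p_331_355": (331, 355, [u - 0.2 for u in base]),
            "p_383_413": (383, 413, [u * 1.6 - 3.0 for u in base]),  # strong
            "p_120_140": (120, 140, [u - 0.6 for u in base]),
        }
        diff, _ = differential_hdx(uptake_table(apo, "apo"),
                                   uptake_table(bound, "bound"))
        ranked = (diff.drop_duplicates("peptide_id")
                  .sort_values("summed_delta_Da", ascending=False))
        assert ranked.iloc[0]["peptide_id"] == "p_383_413"
        assert ranked.iloc[0]["classification"] == "protected"

    def test_sem_propagates_in_quadrature(self):
        pep = {"p1": (1, 10, [0, 1, 2, 3, 4, 5])}
        diff, _ = differential_hdx(uptake_table(pep, "apo"),
                                   uptake_table(pep, "bound"))
        assert diff["sem"].iloc[0] == pytest.approx(np.sqrt(2) * 0.05)


class TestBimodalFit:
    def test_symmetric_equal_weight_split(self):
        ds = synthgen.gen_hdx_bimodal(f1=0.5, n_draws=20000, seed=0)
        fit = fit_bimodal(ds.centers, ds.intensity)
        assert fit.n_populations == 2
        assert fit.f1 == pytest.approx(0.5, abs=0.02)

    def test_thirty_percent_low_uptake_population(self):
        """Truth f1 = 0.30 recovered within ±0.05 (mean over seeds)."""
        f1s = []
        for seed in range(10):
            ds = synthgen.gen_hdx_bimodal(f1=0.30, n_draws=1000, seed=seed)
            fit = fit_bimodal(ds.centers, ds.intensity, seed=seed)
            assert fit.n_populations == 2
            f1s.append(fit.f1)
        assert 0.25 <= np.mean(f1s) <= 0.35

    def test_unimodal_selects_one_population(self):
        ds = synthgen.gen_hdx_bimodal(f1=0.0, n_draws=1000, seed=1)
        fit = fit_bimodal(ds.centers, ds.intensity)
        assert fit.n_populations == 1
        assert fit.f1 == 1.0

    def test_no_false_bimodality_across_seeds(self):
        """BIC keeps one population on unimodal draws in >= 95% of seeds."""
        false_calls = 0
        for seed in range(20):
            ds = synthgen.gen_hdx_bimodal(f1=1.0, n_draws=1000, seed=seed)
            if fit_bimodal(ds.centers, ds.intensity).n_populations == 2:
                false_calls += 1
        assert false_calls <= 1

    def test_unresolvable_modes_flagged(self):
        # separation under half the pooled width -> not two claimable modes
        assert modes_unidentifiable([10.0, 10.25], [1.5, 1.5])
        assert not modes_unidentifiable([8.0, 11.0], [0.6, 0.6])
        # boundary: separation exactly half the pooled width is claimable
        assert not modes_unidentifiable([10.0, 10.75], [1.5, 1.5])
        # BIC selection keeps one population on near-degenerate truth
        ds = synthgen.gen_hdx_bimodal(means_Da=(10.0, 10.25), widths_Da=(1.5, 1.5),
                                      f1=0.5, n_draws=20000, seed=3)
        assert fit_bimodal(ds.centers, ds.intensity).n_populations == 1
        # a forced two-population fit reports the flag state it computes
        forced = fit_bimodal(ds.centers, ds.intensity, n_populations=2)
        assert forced.unidentifiable == modes_unidentifiable(forced.means, forced.widths)

    def test_population_fractions_partition(self):
        ds = synthgen.gen_hdx_bimodal(f1=0.3, n_draws=5000, seed=2)
        fit = fit_bimodal(ds.centers, ds.intensity)
        assert fit.n_populations == 2
        f2 = fit.areas[1] / fit.areas.sum()
        assert fit.f1 + f2 == pytest.approx(1.0, abs=1e-12)
        assert np.all(fit.areas >= 0)
        assert fit.means[0] < fit.means[1]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            fit_bimodal(np.arange(5.0), np.ones(5))


class TestUptakeSummary:
    def _diff(self, peptides):
        rows = []
        for pid, (s, e, delta) in peptides.items():
            rows.append(dict(peptide_id=pid, start=s, end=e, timepoint_h=0.5,
                             delta_Da=delta, sem=0.1, summed_delta_Da=delta,
                             classification="no-change"))
        return pd.DataFrame(rows)

    def test_single_peptide(self):
        m = uptake_summary(self._diff({"p": (3, 12, 1.0)}))
        assert (m.loc[3:12] == 1.0).all()
        assert m.loc[1:2].isna().all()

    def test_overlap_averages(self):
        m = uptake_summary(self._diff({"a": (1, 10, 1.0), "b": (6, 15, 3.0)}))
        assert (m.loc[6:10] == 2.0).all()
        assert (m.loc[1:5] == 1.0).all()
        assert (m.loc[11:15] == 3.0).all()

    def test_disjoint_piecewise_constant(self):
        m = uptake_summary(self._diff({"a": (1, 5, 1.0), "b": (10, 12, -2.0)}))
        assert (m.loc[1:5] == 1.0).all()
        assert m.loc[6:9].isna().all()
        assert (m.loc[10:12] == -2.0).all()

    def test_order_invariance(self):
        peps = {"a": (1, 10, 1.0), "b": (6, 15, 3.0), "c": (2, 4, -1.0)}
        m1 = uptake_summary(self._diff(peps))
        m2 = uptake_summary(self._diff(dict(reversed(list(peps.items())))))
        pd.testing.assert_series_equal(m1, m2)
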