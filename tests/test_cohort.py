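"""Cross-section stack construction: hand enumerations and invariants."""

import numpy as np
import pandas as pd
import pytest

from seqbenefit.cohort import (
    LongTableCovariates,
    build_never_treated_stack,
    build_offer_snapshots,
    build_treated_stack,
    snapshot_covariates,
)
from seqbenefit.simulate import OfferStream


def _episodes(rows):
    """rows: (pid, s_entry, X, delta, treated, T, zstar, post_time, post_delta)"""
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "s_entry", "X", "delta", "treated", "T", "Zstar", "post_time", "post_delta"],
    )
    df["censor_admin"] = 1 - df["delta"] - df["treated"]
    return df


def _flat_measurements(pids, z=0.0):
    return pd.DataFrame({"patient_id": pids, "t": 0.0, "Z": z})


class TestNeverTreatedStack:
    def test_death_enumeration(self):
        """Death at t=0.10, dates {0, 0.04, 0.08}: events at u 0.10/0.06/0.02."""
        eps = _episodes([(0, 0.0, 0.10, 1, 0, np.nan, np.nan, np.nan, 0)])
        cov = LongTableCovariates(_flat_measurements([0]), ["Z"])
        st = build_never_treated_stack(eps, cov, np.array([0.0, 0.04, 0.08]), 3.0)
        assert len(st.rows) == 3
        assert np.allclose(sorted(st.rows["u_stop"]), [0.02, 0.06, 0.10])
        assert st.rows["event"].sum() == 3

    def test_treatment_becomes_artificial_censoring(self):
        eps = _episodes([(0, 0.0, 0.05, 0, 1, 0.05, 0.3, 2.0, 1)])
        cov = LongTableCovariates(_flat_measurements([0]), ["Z"])
        st = build_never_treated_stack(eps, cov, np.array([0.04]), 3.0)
        assert len(st.rows) == 1
        r = st.rows.iloc[0]
        assert r["u_stop"] == pytest.approx(0.01)
        assert r["event"] == 0 and r["artificial_censor"] == 1

    def test_late_entry_excluded(self):
        eps = _episodes([(0, 0.5, 2.0, 1, 0, np.nan, np.nan, np.nan, 0)])
        cov = LongTableCovariates(_flat_measurements([0]), ["Z"])
        st = build_never_treated_stack(eps, cov, np.array([0.2]), 3.0)
        assert len(st.rows) == 0

    def test_ineligible_excluded(self):
        eps = _episodes([(0, 0.0, 2.0, 1, 0, np.nan, np.nan, np.nan, 0)])
        cov = LongTableCovariates(_flat_measurements([0], z=-1.5), ["Z"])
        st = build_never_treated_stack(eps, cov, np.array([0.2]), 3.0)
        assert len(st.rows) == 0
        assert st.provenance["n_excluded_ineligible"] == 1

    def test_person_time_brute_force(self, pop500, default_cfg):
        """Total never-treated person-time equals a per-(patient, date)
        enumeration on a 5-patient subset."""
        from seqbenefit.cohort import PopulationCovariates

        pop = pop500
        sub = pop.episodes.iloc[:5]
        dates = pop.offer_stream.dates_coarse
        st = build_never_treated_stack(
            sub, PopulationCovariates(pop), dates, 3.0,
            eligibility_threshold=pop.config.eligibility_threshold,
        )
        expected = 0.0
        count = 0
        for _, ep in sub.iterrows():
            for c in dates:
                sk = c - ep.s_entry
                if sk < 0 or ep.X <= sk:
                    continue
                if pop.z_at([int(ep.patient_id)], [sk])[0] <= -1:
                    continue
                expected += min(ep.X - sk, 3.0)
                count += 1
        assert len(st.rows) == count
        assert st.rows["u_stop"].sum() == pytest.approx(expected, rel=1e-9)

    def test_stack_invariants(self, stacks500):
        rows = stacks500.never.rows
        assert (rows["u_stop"] <= 3.0 + 1e-12).all()
        assert not rows.duplicated(["patient_id", "k"]).any()
        # each row explained by exactly one of event/artificial/administrative
        assert ((rows["event"] + rows["artificial_censor"]) <= 1).all()

    def test_coarse_subset_of_fine(self, pop500, default_cfg):
        from seqbenefit.cohort import PopulationCovariates

        cov = PopulationCovariates(pop500)
        sub = pop500.episodes.iloc[:40]
        coarse = build_never_treated_stack(sub, cov, np.array([0.04, 0.08]), 3.0)
        fine = build_never_treated_stack(
            sub, cov, np.array([0.04, 0.05, 0.06, 0.07, 0.08]), 3.0
        )
        merged = fine.rows.merge(
            coarse.rows, on=["patient_id", "cs_date"], suffixes=("_f", "_c")
        )
        assert len(merged) == len(coarse.rows)
        assert np.allclose(merged["u_stop_f"], merged["u_stop_c"])


def _stream(dates_fine, offers=None):
    if offers is None:
        offers = pd.DataFrame(
            {
                "date_idx": np.arange(dates_fine.size),
                "date": dates_fine,
                "Zstar": 0.0,
                "patient_id": -1,
            }
        )
    return OfferStream(dates_coarse=dates_fine[::4], dates_fine=dates_fine, offers=offers)


class TestTreatedStack:
    def test_rounding_to_fine_date(self):
        eps = _episodes([(0, 0.0, 0.05, 0, 1, 0.05, 0.3, 1.2, 1)])
        cov = LongTableCovariates(_flat_measurements([0]), ["Z"])
        stream = _stream(np.round(np.arange(0, 9, 0.01), 10))
        st = build_treated_stack(eps, cov, stream, 3.0, spacing_fine=0.01)
        assert len(st.rows) == 1
        r = st.rows.iloc[0]
        assert r["cs_date"] == pytest.approx(0.05)
        assert r["u_stop"] == pytest.approx(1.2) and r["event"] == 1

    def test_two_treatments_same_date_are_separate_cross_sections(self):
        eps = _episodes(
            [
                (0, 0.0, 1.0, 0, 1, 1.0, 0.5, 0.8, 1),
                (1, 0.5, 0.5, 0, 1, 0.5, -0.2, 2.5, 1),
            ]
        )
        cov = LongTableCovariates(_flat_measurements([0, 1]), ["Z"])
        stream = _stream(np.round(np.arange(0, 9, 0.01), 10))
        st = build_treated_stack(eps, cov, stream, 3.0, spacing_fine=0.01)
        assert len(st.rows) == 2
        both = st.rows[st.rows["cs_date"] == 1.0]
        assert len(both) == 2
        assert sorted(both["offer_seq"]) == [0, 1]
        assert set(both["Zstar"]) == {0.5, -0.2}

    def test_beyond_window_skipped(self):
        eps = _episodes([(0, 8.0, 1.5, 0, 1, 1.5, 0.3, 0.4, 1)])  # calendar 9.5
        cov = LongTableCovariates(_flat_measurements([0]), ["Z"])
        stream = _stream(np.round(np.arange(0, 9, 0.01), 10))
        st = build_treated_stack(eps, cov, stream, 3.0, spacing_fine=0.01)
        assert len(st.rows) == 0
        assert st.provenance["n_outside_date_window"] == 1


class TestSnapshots:
    def test_locf(self):
        meas = pd.DataFrame({"patient_id": [0, 0], "t": [0.0, 0.5], "Z": [1.0, 2.0]})
        out = snapshot_covariates(meas, [0, 0, 0], [0.7, 0.5, 0.2], ["Z"])
        assert list(out["Z"]) == [2.0, 2.0, 1.0]

    def test_missing_before_first_measurement(self):
        meas = pd.DataFrame({"patient_id": [0], "t": [1.0], "Z": [1.0]})
        out = snapshot_covariates(meas, [0], [0.5], ["Z"])
        assert out["Z"].isna().all()

    def test_grid_source_matches_path(self, pop500):
        from seqbenefit.cohort import PopulationCovariates

        cov = PopulationCovariates(pop500)
        t = np.array([0.0, 1.234, 5.678])
        snap = cov.snapshot([2, 2, 2], t)
        j = np.floor(t / pop500.config.grid_dt + 1e-9).astype(int)
        assert np.allclose(snap["Z"], pop500.z_paths[2, j])


class TestOfferSnapshots:
    def test_recipient_flagged_and_at_risk(self, pop500, default_cfg):
        snaps = build_offer_snapshots(
            pop500.episodes,
            __import__("seqbenefit.cohort", fromlist=["PopulationCovariates"]).PopulationCovariates(pop500),
            pop500.offer_stream,
        )
        treated_pids = set(np.flatnonzero(pop500.treated))
        flagged = snaps[snaps["treated_flag"] == 1]
        assert set(flagged["patient_id"]).issubset(treated_pids)
        # exactly one recipient row per delivered, eligible offer
        assert flagged.groupby("offer_row").size().max() == 1
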