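"""Rule engine: worked examples, brute-force oracles, invariance properties.

The oracle functions below re-derive events by naive pairwise enumeration —
no sorting-based block logic, no shared code with the implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ubcphen.phenotyping import (
    CYSTECTOMY,
    EXAM,
    EXAM_RULE,
    INTERVENTION_CATEGORIES,
    IVC,
    IVC_GAP_RULE,
    RADIOTHERAPY,
    SYSTEMIC_CHEMO,
    TURBT,
    TURBT_RULE,
    CodeMap,
    WindowConfig,
    call_progression,
    call_recurrence,
    classify_episodes,
    classify_invasiveness,
    deduplicate_events,
    derive_candidate_events,
    derive_phenotypes,
)

W = WindowConfig()

ALL_CODES = [
    "M42", "M421", "M45", "M451", "M494", "M495", "M34", "M341",
    "X65", "X651", "X72", "X292", "X298", "X308", "X352",
]

# explicit enumerated lookup table (the brute-force classification oracle)
ORACLE_TABLE = {}
for prefix, cat in [("M42", TURBT), ("M45", EXAM), ("M34", CYSTECTOMY),
                    ("X65", RADIOTHERAPY), ("X72", SYSTEMIC_CHEMO)]:
    ORACLE_TABLE[prefix] = cat
    for digit in "0123456789":
        ORACLE_TABLE[prefix + digit] = cat
for code, cat in [("M494", IVC), ("M495", IVC), ("X292", SYSTEMIC_CHEMO),
                  ("X298", SYSTEMIC_CHEMO), ("X308", SYSTEMIC_CHEMO),
                  ("X352", SYSTEMIC_CHEMO)]:
    ORACLE_TABLE[code] = cat


def oracle_classify(code):
    return ORACLE_TABLE.get(code)


def oracle_candidates(eps, w=W):
    """Set of (day, rule) by naive enumeration against the three rules."""
    events = set()
    for d, cat, _ in eps:
        if cat == TURBT:
            events.add((d, TURBT_RULE))
    ivc_days = [d for d, cat, _ in eps if cat == IVC]
    for d in ivc_days:
        earlier = [e for e in ivc_days if e < d]
        if earlier and d - max(earlier) > w.ivc_gap_days:
            events.add((d, IVC_GAP_RULE))
    for d, cat, _ in eps:
        if cat == EXAM and any(
            c in INTERVENTION_CATEGORIES and 0 <= d2 - d <= w.followup_window_days
            for d2, c, _ in eps
        ):
            events.add((d, EXAM_RULE))
    return events


def oracle_dedup(days, independence=W.independence_days):
    """Minimal left-anchored covering set by repeated minimum extraction."""
    kept, remaining = [], sorted(set(days))
    while remaining:
        d = remaining[0]
        kept.append(d)
        remaining = [x for x in remaining if x - d > independence]
    return kept


def oracle_recurrence_count(eps, index_day=0, w=W):
    days = [d for d, _ in oracle_candidates(eps, w)]
    return sum(1 for d in oracle_dedup(days, w.independence_days)
               if d - index_day > w.baseline_window_days)


def oracle_progression(eps, index_day=0, w=W):
    radicals = [d for d, c, _ in eps if c in (CYSTECTOMY, RADIOTHERAPY)]
    for d, cat, _ in eps:
        if cat not in (TURBT, EXAM) or d - index_day <= w.baseline_window_days:
            continue
        if cat == EXAM and (d, EXAM_RULE) not in oracle_candidates(eps, w):
            continue
        if any(0 <= r - d <= w.followup_window_days for r in radicals):
            return True
    return False


def oracle_invasiveness(eps, index_day=0, w=W):
    hit = any(
        c in (CYSTECTOMY, RADIOTHERAPY) and 0 <= d - index_day <= w.invasiveness_window_days
        for d, c, _ in eps
    )
    return "MIBC" if hit else "NMIBC"


def run_impl(eps, index_day=0, w=W):
    """Full per-patient pipeline through the implementation under test."""
    cands = derive_candidate_events(eps, w)
    events = deduplicate_events(cands, w)
    count, flag, _ = call_recurrence(events, index_day, w)
    prog = call_progression(events, eps, index_day, w)
    mibc = classify_invasiveness(eps, index_day, w)
    return cands, events, count, prog, mibc


def to_eps(stream):
    """(day, code) pairs -> (day, category, code), dropping uncategorised."""
    out = []
    for d, code in stream:
        cat = oracle_classify(code)
        if cat is not None:
            out.append((d, cat, code))
    return out


# ---------------------------------------------------------------- classification

class TestClassifyEpisodes:
    @pytest.mark.parametrize(
        "code,category",
        [("M421", TURBT), ("M42", TURBT), ("M494", IVC), ("X721", SYSTEMIC_CHEMO),
         ("X292", SYSTEMIC_CHEMO), ("M341", CYSTECTOMY)],
    )
    def test_known_codes(self, code, category):
        assert CodeMap().lookup(code) == category

    @pytest.mark.parametrize("code", ["M493", "X293", "E851", "M44", "X3521"])
    def test_uncategorised(self, code):
        assert CodeMap().lookup(code) is None

    def test_random_streams_equal_lookup_oracle(self):
        rng = np.random.default_rng(21)
        codes = ALL_CODES + ["M493", "E851", "X299", "W401"]
        cm = CodeMap()
        for code in codes:
            assert cm.lookup(code) == oracle_classify(code)
        sample = rng.choice(codes, size=500)
        df = pd.DataFrame({
            "patient_id": ["p"] * 500,
            "episode_date": pd.Timestamp("2000-01-01"),
            "opcs4_code": sample,
        })
        out = classify_episodes(df, cm)
        expected = [oracle_classify(c) for c in sample if oracle_classify(c) is not None]
        assert list(out["category"]) == expected

    def test_overlapping_categories_rejected(self):
        with pytest.raises(ValueError):
            CodeMap(turbt=frozenset({"M42"}), exam=frozenset({"M42"}))


# ---------------------------------------------------------------- candidate events

class TestDeriveCandidateEvents:
    def test_ivc_gap_starts_one_new_event(self):
        # instillations at 10/50/200: gaps 40 and 150 vs the 120-day rule
        eps = [(10, IVC, "M494"), (50, IVC, "M494"), (200, IVC, "M495")]
        events = derive_candidate_events(eps, W)
        assert [(e.day, e.rule) for e in events] == [(200, IVC_GAP_RULE)]

    def test_exam_without_follower_is_silent(self):
        eps = [(300, EXAM, "M45"), (300 + W.followup_window_days + 1, IVC, "M494")]
        events = derive_candidate_events(eps, W)
        assert all(e.rule != EXAM_RULE for e in events)

    def test_exam_same_day_intervention_counts(self):
        eps = [(300, EXAM, "M45"), (300, IVC, "M494")]
        events = derive_candidate_events(eps, W)
        assert (300, EXAM_RULE) in {(e.day, e.rule) for e in events}

    def test_exam_boundary_day_inclusive(self):
        eps = [(0, EXAM, "M45"), (W.followup_window_days, CYSTECTOMY, "M34")]
        assert {(e.day, e.rule) for e in derive_candidate_events(eps, W)} == {(0, EXAM_RULE)}

    def test_every_turbt_is_an_event(self):
        eps = [(5, TURBT, "M42"), (400, TURBT, "M421")]
        assert [(e.day, e.rule) for e in derive_candidate_events(eps, W)] == [
            (5, TURBT_RULE), (400, TURBT_RULE)]

    def test_random_streams_equal_pairwise_oracle(self):
        rng = np.random.default_rng(33)
        days = [0, 30, 95, 121, 200, 250, 290, 400, 500]
        for _ in range(800):
            size = rng.integers(1, 13)
            stream = [(int(rng.choice(days)), str(rng.choice(ALL_CODES))) for _ in range(size)]
            eps = to_eps(stream)
            impl = {(e.day, e.rule) for e in derive_candidate_events(eps, W)}
            assert impl == oracle_candidates(eps, W)


# ---------------------------------------------------------------- dedup

class TestDeduplicateEvents:
    def test_chain_merge(self):
        from ubcphen.phenotyping import CandidateEvent

        evs = [CandidateEvent(0, TURBT_RULE), CandidateEvent(60, TURBT_RULE),
               CandidateEvent(200, TURBT_RULE)]
        kept = deduplicate_events(evs, W)
        assert [e.day for e in kept] == [0, 200]
        assert len(kept[0].members) == 2

    def test_single_event_identity(self):
        from ubcphen.phenotyping import CandidateEvent

        kept = deduplicate_events([CandidateEvent(42, TURBT_RULE)], W)
        assert [e.day for e in kept] == [42]

    @given(st.lists(st.integers(0, 1000), min_size=0, max_size=10))
    def test_matches_minimum_extraction_oracle(self, days):
        from ubcphen.phenotyping import CandidateEvent

        evs = [CandidateEvent(d, TURBT_RULE) for d in days]
        kept = [e.day for e in deduplicate_events(evs, W)]
        assert kept == oracle_dedup(days)

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=10))
    def test_retained_pairwise_gap(self, days):
        from ubcphen.phenotyping import CandidateEvent

        evs = [CandidateEvent(d, TURBT_RULE) for d in days]
        kept = [e.day for e in deduplicate_events(evs, W)]
        assert all(b - a > W.independence_days for a, b in zip(kept, kept[1:]))


# ---------------------------------------------------------------- calls

class TestCallRecurrence:
    def test_index_block_not_counted(self):
        eps = [(5, TURBT, "M42"), (200, TURBT, "M42")]
        events = deduplicate_events(derive_candidate_events(eps, W), W)
        count, flag, first = call_recurrence(events, 0, W)
        assert (count, flag, first) == (1, True, 200)

    def test_only_index_block(self):
        eps = [(5, TURBT, "M42"), (40, TURBT, "M42")]
        events = deduplicate_events(derive_candidate_events(eps, W), W)
        count, flag, first = call_recurrence(events, 0, W)
        assert (count, flag, first) == (0, False, None)


class TestCallProgression:
    def test_turbt_then_cystectomy(self):
        eps = [(200, TURBT, "M42"), (280, CYSTECTOMY, "M34")]
        events = deduplicate_events(derive_candidate_events(eps, W), W)
        assert call_progression(events, eps, 0, W)

    def test_window_boundary_exclusive_past_end(self):
        eps = [(200, TURBT, "M42"), (200 + W.followup_window_days + 1, CYSTECTOMY, "M34")]
        events = deduplicate_events(derive_candidate_events(eps, W), W)
        assert not call_progression(events, eps, 0, W)

    def test_baseline_turbt_does_not_progress(self):
        eps = [(5, TURBT, "M42"), (40, CYSTECTOMY, "M34")]
        events = deduplicate_events(derive_candidate_events(eps, W), W)
        assert not call_progression(events, eps, 0, W)


class TestClassifyInvasiveness:
    def test_early_radiotherapy_is_mibc(self):
        assert classify_invasiveness([(40, RADIOTHERAPY, "X65")], 0, W) == "MIBC"

    def test_no_radical_treatment_is_nmibc(self):
        eps = [(5, TURBT, "M42"), (300, TURBT, "M42")]
        assert classify_invasiveness(eps, 0, W) == "NMIBC"

    def test_late_cystectomy_is_not_mibc(self):
        eps = [(W.invasiveness_window_days + 1, CYSTECTOMY, "M34")]
        assert classify_invasiveness(eps, 0, W) == "NMIBC"


# ---------------------------------------------------------------- oracle sweeps

class TestOracleEquivalence:
    def test_exhaustive_small_streams(self):
        # all streams of <= 2 episodes over the full code list x 5 dates
        days = [0, 95, 200, 290, 500]
        options = [(d, c) for d in days for c in ALL_CODES]
        singles = [[o] for o in options]
        pairs = [list(p) for p in itertools.combinations_with_replacement(options, 2)]
        for stream in singles + pairs:
            eps = to_eps(stream)
            _, _, count, prog, mibc = run_impl(eps)
            assert count == oracle_recurrence_count(eps)
            assert prog == oracle_progression(eps)
            assert mibc == oracle_invasiveness(eps)

    def test_random_medium_streams(self):
        rng = np.random.default_rng(55)
        days = list(range(0, 700, 13))
        for _ in range(1500):
            size = rng.integers(3, 9)
            stream = [(int(rng.choice(days)), str(rng.choice(ALL_CODES))) for _ in range(size)]
            eps = to_eps(stream)
            _, _, count, prog, mibc = run_impl(eps)
            assert count == oracle_recurrence_count(eps)
            assert prog == oracle_progression(eps)
            assert mibc == oracle_invasiveness(eps)


# ---------------------------------------------------------------- properties

@st.composite
def episode_streams(draw):
    size = draw(st.integers(0, 8))
    days = draw(st.lists(st.integers(0, 800), min_size=size, max_size=size))
    codes = draw(st.lists(st.sampled_from(ALL_CODES), min_size=size, max_size=size))
    return list(zip(days, codes))


class TestProperties:
    @given(episode_streams())
    def test_permutation_invariance(self, stream):
        eps = to_eps(stream)
        rev = list(reversed(eps))
        assert run_impl(eps)[2:] == run_impl(rev)[2:]

    @given(episode_streams())
    @settings(max_examples=60, deadline=None)
    def test_progression_implies_recurrence(self, stream):
        # enforced at the phenotype-row level: a progression anchor may be
        # absorbed into a baseline-window event, so raw counts can be 0
        episodes = pd.DataFrame(
            {
                "patient_id": ["p"] * len(stream),
                "episode_date": [
                    np.datetime64("2000-01-01") + np.timedelta64(d, "D") for d, _ in stream
                ],
                "opcs4_code": [c for _, c in stream],
            }
        )
        index_dates = pd.Series(pd.to_datetime(["2000-01-01"]), index=["p"])
        pheno = derive_phenotypes(episodes, index_dates)
        row = pheno.iloc[0]
        if row["progression_flag"]:
            assert row["recurrence_flag"] and row["recurrence_count"] >= 1

    @given(episode_streams(), st.integers(120, 400))
    def test_followup_window_monotone_in_progression(self, stream, wider):
        eps = to_eps(stream)
        base = WindowConfig()
        wide = WindowConfig(followup_window_days=max(wider, base.followup_window_days))
        _, _, _, prog_base, _ = run_impl(eps, w=base)
        _, _, _, prog_wide, _ = run_impl(eps, w=wide)
        assert prog_wide or not prog_base

    @given(episode_streams(), st.integers(91, 400))
    def test_independence_window_antitone_in_recurrence(self, stream, wider):
        eps = to_eps(stream)
        base = WindowConfig()
        wide = WindowConfig(independence_days=max(wider, base.independence_days))
        count_base = run_impl(eps, w=base)[2]
        count_wide = run_impl(eps, w=wide)[2]
        assert count_wide <= count_base


# ---------------------------------------------------------------- frame level

class TestDerivePhenotypes:
    def test_frame_output_and_audit(self):
        episodes = pd.DataFrame(
            {
                "patient_id": ["a", "a", "b"],
                "episode_date": pd.to_datetime(["2001-01-05", "2001-09-01", "2003-02-01"]),
                "opcs4_code": ["M42", "M42", "M45"],
            }
        )
        index_dates = pd.Series(
            pd.to_datetime(["2001-01-01", "2003-01-01"]), index=["a", "b"]
        )
        pheno, audit = derive_phenotypes(episodes, index_dates, audit=True)
        row_a = pheno.set_index("patient_id").loc["a"]
        assert row_a["recurrence_count"] == 1
        assert bool(row_a["recurrence_flag"])
        assert not bool(pheno.set_index("patient_id").loc["b"]["recurrence_flag"])
        assert set(audit["patient_id"]) == {"a"}

    def test_windows_validation(self):
        with pytest.raises(ValueError):
            WindowConfig(ivc_gap_days=0)
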