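"""Temporal rule engine over coded in-hospital interventions.

Classifies OPCS4-coded episodes into procedure categories and derives, per
patient, tumour-event candidates, independent events, recurrence counts,
progression and baseline invasiveness.

Event rules
-----------
1. A bladder-tumour resection (TURBT) episode is itself an event.
2. Within a patient's intravesical-chemotherapy sequence, a gap longer than
   ``ivc_gap_days`` starts a new event, dated at the first instillation of
   the new block; the first block is attached to the preceding event or to
   the index diagnosis and yields no event of its own.
3. A bladder examination followed by any intervention (intravesical chemo,
   cystectomy, radiotherapy, systemic chemo) within ``followup_window_days``
   is an event, dated at the examination.

Candidate events closer than ``independence_days`` are merged (earliest date
kept). Events inside the index window are primary treatment, not recurrence.
Progression = a post-baseline TURBT/examination event followed by cystectomy
or radiotherapy within the follow-up window; progression implies recurrence.
Invasiveness: cystectomy or radiotherapy within ``invasiveness_window_days``
of the index diagnosis marks a muscle-invasive baseline tumour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CodeMap",
    "WindowConfig",
    "CandidateEvent",
    "IndependentEvent",
    "TURBT",
    "EXAM",
    "IVC",
    "CYSTECTOMY",
    "RADIOTHERAPY",
    "SYSTEMIC_CHEMO",
    "INTERVENTION_CATEGORIES",
    "TURBT_RULE",
    "IVC_GAP_RULE",
    "EXAM_RULE",
    "classify_episodes",
    "derive_candidate_events",
    "deduplicate_events",
    "call_recurrence",
    "call_progression",
    "classify_invasiveness",
    "derive_phenotypes",
]

TURBT = "TURBT"
EXAM = "EXAM"
IVC = "IVC"
CYSTECTOMY = "CYSTECTOMY"
RADIOTHERAPY = "RADIOTHERAPY"
SYSTEMIC_CHEMO = "SYSTEMIC_CHEMO"

#: categories that count as an "intervention" for the examination rule
INTERVENTION_CATEGORIES = frozenset({IVC, CYSTECTOMY, RADIOTHERAPY, SYSTEMIC_CHEMO})

TURBT_RULE = "TURBT_RULE"
IVC_GAP_RULE = "IVC_GAP_RULE"
EXAM_RULE = "EXAM_RULE"


@dataclass(frozen=True)
class CodeMap:
    """Procedure-category code sets.

    Three-character codes match any four-character extension by prefix;
    four-character codes match exactly.
    """

    turbt: frozenset = frozenset({"M42"})
    exam: frozenset = frozenset({"M45"})
    ivc: frozenset = frozenset({"M494", "M495"})
    cystectomy: frozenset = frozenset({"M34"})
    radiotherapy: frozenset = frozenset({"X65"})
    systemic_chemo: frozenset = frozenset({"X72", "X292", "X298", "X308", "X352"})

    def __post_init__(self) -> None:
        groups = self.as_dict()
        seen: set = set()
        for codes in groups.values():
            if seen & set(codes):
                raise ValueError("procedure categories must be disjoint")
            seen |= set(codes)

    def as_dict(self) -> Dict[str, frozenset]:
        return {
            TURBT: self.turbt,
            EXAM: self.exam,
            IVC: self.ivc,
            CYSTECTOMY: self.cystectomy,
            RADIOTHERAPY: self.radiotherapy,
            SYSTEMIC_CHEMO: self.systemic_chemo,
        }

    def lookup(self, code: str) -> Optional[str]:
        """Category of an OPCS4 code, or None when uncategorised."""
        for category, codes in self.as_dict().items():
            for c in codes:
                if len(c) == 4:
                    if code == c:
                        return category
                elif code[:3] == c:
                    return category
        return None


@dataclass(frozen=True)
class WindowConfig:
    """Day-count interpretations of the algorithm's month-based windows."""

    ivc_gap_days: int = 120           # "> 4 months" between instillations
    followup_window_days: int = 183   # "within 6 months"
    independence_days: int = 91       # "> 3 months" between events
    baseline_window_days: int = 91    # index / primary-treatment window
    invasiveness_window_days: int = 183

    def __post_init__(self) -> None:
        for name in (
            "ivc_gap_days",
            "followup_window_days",
            "independence_days",
            "baseline_window_days",
            "invasiveness_window_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CandidateEvent:
    day: int
    rule: str
    codes: Tuple[str, ...] = ()


@dataclass
class IndependentEvent:
    """A retained event after merging; ``members`` keeps the absorbed
    candidates (including the event itself) as (day, rule) pairs."""

    day: int
    members: List[Tuple[int, str]] = field(default_factory=list)

    @property
    def rules(self) -> frozenset:
        return frozenset(rule for _, rule in self.members)


def classify_episodes(episodes: pd.DataFrame, code_map: CodeMap = CodeMap()) -> pd.DataFrame:
    """Attach a ``category`` column; uncategorised codes are dropped.

    Expects columns ``patient_id``, ``episode_date``, ``opcs4_code``.
    """
    out = episodes.copy()
    out["category"] = [code_map.lookup(c) for c in out["opcs4_code"].astype(str)]
    dropped = out["category"].isna()
    if dropped.any():
        logger.debug(
            "dropping %d uncategorised episodes (codes %s)",
            int(dropped.sum()),
            sorted(out.loc[dropped, "opcs4_code"].unique()),
        )
    return out.loc[~dropped].reset_index(drop=True)


def derive_candidate_events(
    episodes: Sequence[Tuple[int, str, str]],
    windows: WindowConfig = WindowConfig(),
) -> List[CandidateEvent]:
    """Candidate tumour events for one patient.

    ``episodes`` are (day, category, code) triples for a single patient;
    input order is irrelevant. "Within" windows are inclusive of day 0 and of
    the boundary day; "longer than" gaps are strict.
    """
    eps = sorted(episodes, key=lambda e: e[0])
    events: List[CandidateEvent] = []

    # rule 1: every resection is an event at its own date
    for day, cat, code in eps:
        if cat == TURBT:
            events.append(CandidateEvent(day, TURBT_RULE, (code,)))

    # rule 2: instillation blocks split on a strict gap; each later block
    # starts an event at its first instillation, the first block does not
    ivc = [(day, code) for day, cat, code in eps if cat == IVC]
    for i in range(1, len(ivc)):
        if ivc[i][0] - ivc[i - 1][0] > windows.ivc_gap_days:
            events.append(CandidateEvent(ivc[i][0], IVC_GAP_RULE, (ivc[i][1],)))

    # rule 3: examination followed by an intervention inside the window
    for day, cat, code in eps:
        if cat != EXAM:
            continue
        followers = tuple(
            c
            for d, c2, c in eps
            if c2 in INTERVENTION_CATEGORIES and 0 <= d - day <= windows.followup_window_days
        )
        if followers:
            events.append(CandidateEvent(day, EXAM_RULE, (code,) + followers))

    events.sort(key=lambda e: (e.day, e.rule))
    return events


def deduplicate_events(
    events: Sequence[CandidateEvent],
    windows: WindowConfig = WindowConfig(),
) -> List[IndependentEvent]:
    """Greedy left-anchored merge of candidates closer than the independence gap.

    The earliest date of a run is kept; retained events end up pairwise more
    than ``independence_days`` apart.
    """
    merged: List[IndependentEvent] = []
    for ev in sorted(events, key=lambda e: (e.day, e.rule)):
        if merged and ev.day - merged[-1].day <= windows.independence_days:
            merged[-1].members.append((ev.day, ev.rule))
        else:
            merged.append(IndependentEvent(day=ev.day, members=[(ev.day, ev.rule)]))
    return merged


def call_recurrence(
    events: Sequence[IndependentEvent],
    index_day: int,
    windows: WindowConfig = WindowConfig(),
) -> Tuple[int, bool, Optional[int]]:
    """(count, flag, first event day) of recurrences after the index block.

    Independent events no later than ``baseline_window_days`` after the index
    diagnosis belong to primary treatment and are not counted.
    """
    post = [e for e in events if e.day - index_day > windows.baseline_window_days]
    count = len(post)
    return count, count >= 1, (post[0].day if post else None)


def call_progression(
    events: Sequence[IndependentEvent],
    episodes: Sequence[Tuple[int, str, str]],
    index_day: int,
    windows: WindowConfig = WindowConfig(),
) -> bool:
    """True when a post-baseline resection/examination event is followed by
    cystectomy or radiotherapy within the follow-up window.

    Checked per merged member so an absorbed resection keeps its own date.
    """
    radical = sorted(d for d, cat, _ in episodes if cat in (CYSTECTOMY, RADIOTHERAPY))
    if not radical:
        return False
    for ev in events:
        for day, rule in ev.members:
            if rule not in (TURBT_RULE, EXAM_RULE):
                continue
            if day - index_day <= windows.baseline_window_days:
                continue
            if any(0 <= r - day <= windows.followup_window_days for r in radical):
                return True
    return False


def classify_invasiveness(
    episodes: Sequence[Tuple[int, str, str]],
    index_day: int,
    windows: WindowConfig = WindowConfig(),
) -> str:
    """"MIBC" when cystectomy/radiotherapy follows the index diagnosis within
    the invasiveness window, else "NMIBC"."""
    for day, cat, _ in episodes:
        if cat in (CYSTECTOMY, RADIOTHERAPY) and 0 <= day - index_day <= windows.invasiveness_window_days:
            return "MIBC"
    return "NMIBC"


def _to_day(values: pd.Series) -> np.ndarray:
    return pd.to_datetime(values).values.astype("datetime64[D]").astype(int)


def derive_phenotypes(
    episodes: pd.DataFrame,
    index_dates: pd.Series,
    windows: WindowConfig = WindowConfig(),
    code_map: CodeMap = CodeMap(),
    audit: bool = False,
) -> pd.DataFrame | Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient phenotype table from episode records.

    Parameters
    ----------
    episodes
        Validated episode records (``patient_id``, ``episode_date``,
        ``opcs4_code``).
    index_dates
        Index diagnosis date per patient id (defines every window); patients
        missing an index date are skipped with a warning.
    audit
        Also return the per-patient independent-event log
        (patient_id, event_date, rules).

    Returns
    -------
    DataFrame with columns patient_id, recurrence_count, recurrence_flag,
    progression_flag, mibc_at_baseline, first_recurrence_date
    (and, when ``audit``, a second events DataFrame).
    """
    classified = classify_episodes(episodes, code_map)
    if len(classified):
        day = _to_day(classified["episode_date"])
        by_patient = {
            pid: list(zip(day[idx], classified["category"].values[idx], classified["opcs4_code"].values[idx]))
            for pid, idx in classified.groupby("patient_id").indices.items()
        }
    else:
        by_patient = {}

    index_day = pd.Series(
        pd.to_datetime(index_dates).values.astype("datetime64[D]").astype(int),
        index=index_dates.index,
    )

    rows = []
    audit_rows = []
    for pid, idx_day in index_day.items():
        eps = by_patient.get(pid, [])
        candidates = derive_candidate_events(eps, windows)
        events = deduplicate_events(candidates, windows)
        count, flag, first_day = call_recurrence(events, idx_day, windows)
        progression = call_progression(events, eps, idx_day, windows)
        if progression and not flag:  # progression implies recurrence
            flag, count = True, max(count, 1)
        invasive = classify_invasiveness(eps, idx_day, windows)
        rows.append(
            {
                "patient_id": pid,
                "recurrence_count": count,
                "recurrence_flag": flag,
                "progression_flag": progression,
                "mibc_at_baseline": invasive == "MIBC",
                "first_recurrence_date": (
                    np.datetime64(int(first_day), "D") if first_day is not None else pd.NaT
                ),
            }
        )
        if audit:
            for ev in events:
                audit_rows.append(
                    {
                        "patient_id": pid,
                        "event_date": np.datetime64(int(ev.day), "D"),
                        "rules": "|".join(sorted(ev.rules)),
                        "n_merged": len(ev.members),
                    }
                )

    skipped = set(by_patient) - set(index_day.index)
    if skipped:
        logger.warning("%d patients with episodes but no index date were skipped", len(skipped))

    pheno = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "recurrence_count",
            "recurrence_flag",
            "progression_flag",
            "mibc_at_baseline",
            "first_recurrence_date",
        ],
    )
    if audit:
        audit_df = pd.DataFrame(
            audit_rows, columns=["patient_id", "event_date", "rules", "n_merged"]
        )
        return pheno, audit_df
    return pheno
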