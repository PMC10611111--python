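"""End-to-end orchestration: cohort -> cycles -> feature table -> protocol.

These helpers glue the stage modules together for the CLI, the tests and
the acceptance script.  Each stage is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import AssembledTable, ClassifierConfig, RunResult, assemble_table, run_protocol
from .cohort import Cohort, CohortSpec, simulate_cohort
from .features import FeatureConfig, extract_participant_features
from .preprocess import AX_V, FilterSpec
from .segmentation import GaitCycle, GaitEvents, segment_recording

log = logging.getLogger(__name__)


@dataclass
class SegmentedParticipant:
    participant_id: str
    group: str
    cycles: dict[str, list[GaitCycle]]          # test -> cycles (both sides)
    events: dict[str, dict[str, GaitEvents]]    # test -> side -> events
    qc: dict[str, dict[str, tuple[bool, str]]]  # test -> side -> (ok, reason)
    trunk_v: dict[str, np.ndarray]              # test -> full trunk vertical accel


def segment_participant(participant, filter_spec: FilterSpec = FilterSpec(),
                        trunk_site: str = "L3") -> SegmentedParticipant:
    """Run per-side event detection, quality gating and cycle delineation on
    both tests of one participant."""
    cycles: dict[str, list[GaitCycle]] = {}
    events: dict[str, dict[str, GaitEvents]] = {}
    qc: dict[str, dict[str, tuple[bool, str]]] = {}
    trunk_v: dict[str, np.ndarray] = {}
    for test, recs in participant.recordings.items():
        cycles[test], events[test], qc[test] = [], {}, {}
        trunk_v[test] = recs[trunk_site].accel[:, AX_V]
        for side in ("L", "R"):
            ev, cyc, gate = segment_recording(
                recs[f"shank_{side}"], recs[f"thigh_{side}"], recs[trunk_site],
                test, side, participant.participant_id, filter_spec)
            events[test][side] = ev
            qc[test][side] = gate
            cycles[test].extend(cyc)
            if not gate[0]:
                log.info("QC fail %s/%s/%s: %s", participant.participant_id,
                         test, side, gate[1])
    return SegmentedParticipant(participant.participant_id, participant.group,
                                cycles, events, qc, trunk_v)


def extract_cohort_features(cohort: Cohort,
                            feature_cfg: FeatureConfig = FeatureConfig(),
                            filter_spec: FilterSpec = FilterSpec()
                            ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame, str]]:
    """participant id -> (gait table, tandem table, group); participants
    failing quality gates on both sides of a test are dropped."""
    out: dict[str, tuple[pd.DataFrame, pd.DataFrame, str]] = {}
    for p in cohort.participants:
        seg = segment_participant(p, filter_spec)
        if not seg.cycles["gait"] or not seg.cycles["tandem"]:
            log.warning("participant %s dropped: no usable cycles", p.participant_id)
            continue
        gait_df, tandem_df = extract_participant_features(
            seg.cycles["gait"], seg.cycles["tandem"],
            seg.trunk_v["gait"], seg.trunk_v["tandem"],
            contralateral=seg.events["gait"], cfg=feature_cfg)
        out[p.participant_id] = (gait_df, tandem_df, p.group)
    return out


def cohort_feature_table(cohort: Cohort, seed: int = 0,
                         rows_per_participant: int = 10,
                         feature_cfg: FeatureConfig = FeatureConfig()
                         ) -> AssembledTable:
    feats = extract_cohort_features(cohort, feature_cfg)
    return assemble_table(feats, rng_seed=seed,
                          rows_per_participant=rows_per_participant)


def run_synthetic_protocol(spec: CohortSpec, cfg: ClassifierConfig,
                           table_seed: int = 0) -> tuple[AssembledTable, RunResult]:
    """Simulate, segment, extract, assemble and classify in one call."""
    cohort = simulate_cohort(spec)
    table = cohort_feature_table(cohort, seed=table_seed)
    return table, run_protocol(table, cfg)
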