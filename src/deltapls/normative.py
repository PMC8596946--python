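"""Normative difference-map scoring against matched control subgroups.

Each concussed athlete's parameter maps are referenced to a demographically
matched subgroup of uninjured controls (same sex, same history-of-concussion
status, age within ±2 years).  At every voxel, the subgroup's robust mean
m_s is computed by a Huber location M-estimator (tuning k = 1.35, scale
fixed at 1.4826·MAD), and the athlete's difference score is
Δx_s = x_s − m_s.  The same control subgroup — hence the same m_s — is
reused for all of the athlete's imaging sessions, keeping the longitudinal
baseline consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SESSIONS, ParameterMap, SubjectRecord


class ScoringError(ValueError):
    """Matching or scoring could not be completed for an athlete."""


@dataclass
class MatchCriteria:
    """Control-matching rule: same sex, same HOC, age gap ≤ max_age_gap."""

    max_age_gap: float = 2.0

    def __post_init__(self) -> None:
        if self.max_age_gap < 0:
            raise ValueError("max_age_gap must be non-negative")


@dataclass
class DifferenceMap:
    """Δx_s = x_s − m_s for one athlete/session/modality."""

    subject_id: str
    session: str
    modality: str
    delta_values: np.ndarray
    matched_control_ids: tuple[str, ...]
    m_values: np.ndarray


def match_controls(
    athlete: SubjectRecord,
    controls: list[SubjectRecord],
    criteria: MatchCriteria = MatchCriteria(),
) -> list[str]:
    """Ids of controls matching the athlete on sex, HOC and age (inclusive gap).

    An empty result is returned with a warning; downstream scoring raises.
    """
    matched = [
        c.subject_id
        for c in controls
        if c.sex == athlete.sex
        and c.hoc == athlete.hoc
        and abs(c.age - athlete.age) <= criteria.max_age_gap
    ]
    if not matched:
        warnings.warn(
            f"no matched controls for athlete {athlete.subject_id}",
            stacklevel=2,
        )
    return matched


def huber_location(
    values: np.ndarray,
    k: float = 1.35,
    tol: float = 1e-8,
    max_iter: int = 100,
    axis: int | None = None,
) -> float | np.ndarray:
    """Huber location M-estimate, solved by IRLS from a median start.

    Minimizes sum_i rho_k((x_i − mu)/sigma) with the Huber loss and the
    auxiliary scale sigma = 1.4826·MAD held fixed.  Columns with zero MAD
    fall back to the median (the objective is degenerate there).  With
    ``axis=0`` the estimate is computed independently per column of a 2-D
    array, fully vectorized.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("huber_location requires at least one value")
    scalar_input = axis is None
    if scalar_input:
        x = x.reshape(-1, 1)
    elif axis != 0:
        raise ValueError("only axis=0 (or scalar input) is supported")
    if not np.all(np.isfinite(x)):
        raise ValueError("huber_location requires finite values")

    med = np.median(x, axis=0)
    sigma = 1.4826 * np.median(np.abs(x - med), axis=0)
    degenerate = sigma <= 0
    sigma_safe = np.where(degenerate, 1.0, sigma)

    mu = med.copy()
    for _ in range(max_iter):
        u = (x - mu) / sigma_safe
        absu = np.abs(u)
        w = np.where(absu <= k, 1.0, k / np.maximum(absu, 1e-300))
        new_mu = (w * x).sum(axis=0) / w.sum(axis=0)
        delta = np.max(np.abs(new_mu - mu))
        mu = new_mu
        if delta <= tol * (1.0 + np.max(np.abs(mu))):
            break
    mu = np.where(degenerate, med, mu)
    return float(mu[0]) if scalar_input else mu


def difference_maps(
    athlete_maps: list[ParameterMap],
    control_maps: list[ParameterMap],
    k: float = 1.35,
) -> list[DifferenceMap]:
    """Difference maps for one athlete against a matched control subgroup.

    ``control_maps`` are the subgroup's maps for the same modality; the
    voxelwise robust mean m_s is computed once and subtracted from each of
    the athlete's session maps.
    """
    if len(control_maps) < 3:
        raise ScoringError(
            "matched control subgroup must contain at least 3 maps "
            f"(got {len(control_maps)})"
        )
    if not athlete_maps:
        raise ScoringError("athlete has no maps to score")
    modality = athlete_maps[0].modality
    control_ids = tuple(m.subject_id for m in control_maps)
    stack = np.vstack([m.values for m in control_maps])
    m_values = huber_location(stack, k=k, axis=0)
    out = []
    for pm in athlete_maps:
        if pm.modality != modality:
            raise ScoringError("mixed modalities in athlete maps")
        out.append(
            DifferenceMap(
                subject_id=pm.subject_id,
                session=pm.session,
                modality=modality,
                delta_values=pm.values - m_values,
                matched_control_ids=control_ids,
                m_values=m_values,
            )
        )
    return out


def score_cohort(
    records: list[SubjectRecord],
    maps: list[ParameterMap],
    modality: str,
    criteria: MatchCriteria = MatchCriteria(),
    k: float = 1.35,
    excluded_ids: set[str] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray, pd.DataFrame]:
    """Score every concussed athlete of one modality against matched controls.

    QC-excluded subject ids are removed before matching.  Returns
    ``(athlete_ids, sex, deltas, match_report)`` where ``deltas`` is an
    (athletes, sessions, voxels) array with NaN marking missing sessions
    and ``match_report`` records the matched subgroup size per athlete
    (for comparison with the cohort's expected median of ~29).
    """
    excluded_ids = excluded_ids or set()
    controls = [r for r in records
                if r.group == "control" and r.subject_id not in excluded_ids]
    athletes = [r for r in records
                if r.group == "concussed" and r.subject_id not in excluded_ids]
    ctrl_maps = {
        m.subject_id: m for m in maps
        if m.modality == modality and m.session == "CONTROL"
        and m.subject_id not in excluded_ids
    }
    by_athlete: dict[str, list[ParameterMap]] = {}
    for m in maps:
        if (m.modality == modality and m.session in SESSIONS
                and m.subject_id not in excluded_ids):
            by_athlete.setdefault(m.subject_id, []).append(m)

    athlete_ids, sexes, rows, per_subject = [], [], [], []
    V = next(iter(ctrl_maps.values())).geometry.n_voxels if ctrl_maps else 0
    for rec in athletes:
        amaps = by_athlete.get(rec.subject_id, [])
        if not amaps:
            continue
        matched = match_controls(rec, controls, criteria)
        matched = [cid for cid in matched if cid in ctrl_maps]
        if not matched:
            raise ScoringError(
                f"no matched controls with {modality} maps for athlete "
                f"{rec.subject_id}"
            )
        dmaps = difference_maps(
            amaps, [ctrl_maps[cid] for cid in matched], k=k
        )
        delta_row = np.full((len(SESSIONS), V), np.nan)
        for dm in dmaps:
            delta_row[SESSIONS.index(dm.session)] = dm.delta_values
        athlete_ids.append(rec.subject_id)
        sexes.append(rec.sex)
        per_subject.append(delta_row)
        rows.append({"subject_id": rec.subject_id, "modality": modality,
                     "n_matched": len(matched),
                     "matched_ids": ";".join(matched)})
    if not athlete_ids:
        raise ScoringError(f"no scoreable athletes for modality {modality}")
    deltas = np.stack(per_subject)
    return athlete_ids, np.asarray(sexes), deltas, pd.DataFrame(rows)
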