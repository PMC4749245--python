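"""Per-shock features: AMSA, previous-shock index (PSI) and delta-AMSA.

For the k-th shock of a patient:

    PSI_k    = 0 if k = 1; +1 if shock k-1 succeeded; -1 if it failed
    dAMSA_k  = 0 if k = 1; AMSA_k - AMSA_{k-1} otherwise

Feature combinations: AMSA alone, C1 = AMSA+PSI, C2 = AMSA+dAMSA,
C3 = AMSA+PSI+dAMSA.  Outcome coding: success = 1 (the positive class).

Shocks whose AMSA could not be measured are dropped without re-indexing
(the formulas are defined on actual consecutive shocks); a strict mode
raises instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MalformedSequenceError

#: canonical feature combinations; column order is fixed
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "AMSA": ("amsa",),
    "C1": ("amsa", "psi"),
    "C2": ("amsa", "delta_amsa"),
    "C3": ("amsa", "psi", "delta_amsa"),
}

STRATA = ("first", "subsequent", "all")


@dataclass
class ShockRecord:
    """One defibrillation attempt: features and binary outcome."""

    patient_id: str
    shock_index: int
    amsa: float
    outcome: int  # 1 = success (organised rhythm), 0 = failure
    psi: int = 0
    delta_amsa: float = 0.0

    def __post_init__(self) -> None:
        if self.shock_index < 1:
            raise MalformedSequenceError("shock_index must be >= 1")
        if self.outcome not in (0, 1):
            raise InvalidArgumentError("outcome must be 0 or 1")
        if self.psi not in (-1, 0, 1):
            raise InvalidArgumentError("psi must be in {-1, 0, +1}")
        if self.shock_index == 1 and (self.psi != 0 or self.delta_amsa != 0.0):
            raise MalformedSequenceError("first shocks must have psi = delta_amsa = 0")

    @property
    def is_first(self) -> bool:
        return self.shock_index == 1


@dataclass
class PatientSequence:
    """Ordered shocks of one patient; the unit of train/validation splitting."""

    patient_id: str
    shocks: list[ShockRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [s.shock_index for s in self.shocks]
        if indices != list(range(1, len(self.shocks) + 1)):
            raise MalformedSequenceError(
                f"patient {self.patient_id}: shock indices must be 1..n consecutive, "
                f"got {indices}"
            )
        for s in self.shocks:
            if s.patient_id != self.patient_id:
                raise MalformedSequenceError(
                    f"record patient_id {s.patient_id!r} != sequence {self.patient_id!r}"
                )

    def __len__(self) -> int:
        return len(self.shocks)


def _check_indices(indices: np.ndarray) -> None:
    if indices.size == 0:
        return
    expected = np.arange(1, indices.size + 1)
    if not np.array_equal(indices, expected):
        raise MalformedSequenceError(
            f"shock indices must be 1..n consecutive, got {indices.tolist()}"
        )


def compute_psi(sequence) -> np.ndarray:
    """PSI per shock from an iterable of (shock_index, outcome) pairs.

    Pairs may arrive in any order; the result is aligned to ascending
    shock index.  A gap or duplicate in the indices raises
    :class:`MalformedSequenceError`.
    """
    pairs = sorted((int(k), int(o)) for k, o in sequence)
    indices = np.array([k for k, _ in pairs], dtype=int)
    outcomes = np.array([o for _, o in pairs], dtype=int)
    _check_indices(indices)
    psi = np.zeros(indices.size, dtype=int)
    if indices.size > 1:
        psi[1:] = np.where(outcomes[:-1] == 1, 1, -1)
    return psi


def compute_delta_amsa(sequence) -> np.ndarray:
    """dAMSA per shock from an iterable of (shock_index, amsa) pairs."""
    pairs = sorted(((int(k), float(a)) for k, a in sequence), key=lambda p: p[0])
    indices = np.array([k for k, _ in pairs], dtype=int)
    amsa = np.array([a for _, a in pairs], dtype=float)
    _check_indices(indices)
    delta = np.zeros(indices.size, dtype=float)
    if indices.size > 1:
        delta[1:] = np.diff(amsa)
    return delta


def annotate_sequence(sequence: PatientSequence) -> PatientSequence:
    """Return a copy of the sequence with psi and delta_amsa filled in."""
    pairs_o = [(s.shock_index, s.outcome) for s in sequence.shocks]
    pairs_a = [(s.shock_index, s.amsa) for s in sequence.shocks]
    psi = compute_psi(pairs_o)
    delta = compute_delta_amsa(pairs_a)
    shocks = [
        ShockRecord(s.patient_id, s.shock_index, s.amsa, s.outcome,
                    psi=int(p), delta_amsa=float(d))
        for s, p, d in zip(sequence.shocks, psi, delta)
    ]
    return PatientSequence(sequence.patient_id, shocks)


def sequences_to_frame(sequences) -> pd.DataFrame:
    """Flatten patient sequences into the canonical feature table.

    Columns: patient_id, shock_index, amsa, psi, delta_amsa, outcome.
    PSI and dAMSA are recomputed from the stored outcomes/AMSA so the
    table is always internally consistent.
    """
    rows = []
    for seq in sequences:
        for s in annotate_sequence(seq).shocks:
            rows.append((s.patient_id, s.shock_index, s.amsa, s.psi,
                         s.delta_amsa, s.outcome))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "shock_index", "amsa", "psi", "delta_amsa", "outcome"],
    )


def build_feature_table(
    cohort,
    feature_set: str = "C3",
    stratum: str = "all",
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Per-shock rows for one feature combination, restricted to a stratum.

    Parameters
    ----------
    cohort
        A list of :class:`PatientSequence`, an object with a ``sequences``
        attribute, or a DataFrame with at least patient_id, shock_index,
        amsa, outcome columns.
    feature_set
        One of ``AMSA``, ``C1``, ``C2``, ``C3``.
    stratum
        ``first`` (k = 1), ``subsequent`` (k > 1) or ``all``.
    strict
        When True, rows with unanalysable (NaN) AMSA raise instead of
        being dropped.
    """
    if feature_set not in FEATURE_SETS:
        raise InvalidArgumentError(f"unknown feature set {feature_set!r}")
    if stratum not in STRATA:
        raise InvalidArgumentError(f"unknown stratum {stratum!r}")

    if isinstance(cohort, pd.DataFrame):
        frame = cohort.copy()
        if "psi" not in frame.columns or "delta_amsa" not in frame.columns:
            frame = _annotate_frame(frame)
    else:
        sequences = getattr(cohort, "sequences", cohort)
        frame = sequences_to_frame(sequences)

    cols = list(FEATURE_SETS[feature_set])
    bad = frame[cols].isna().any(axis=1)
    if bad.any():
        if strict:
            raise MalformedSequenceError(
                f"{int(bad.sum())} shocks have unanalysable features"
            )
        frame = frame[~bad]

    if stratum == "first":
        frame = frame[frame["shock_index"] == 1]
    elif stratum == "subsequent":
        frame = frame[frame["shock_index"] > 1]
    if frame.empty:
        warnings.warn(f"empty {stratum!r} stratum", stacklevel=2)
    out_cols = ["patient_id", "shock_index", *cols, "outcome"]
    return frame[out_cols].reset_index(drop=True)


def _annotate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.sort_values(["patient_id", "shock_index"]).reset_index(drop=True)
    psi_parts, delta_parts = [], []
    for _, grp in frame.groupby("patient_id", sort=False):
        psi_parts.append(compute_psi(zip(grp["shock_index"], grp["outcome"])))
        delta_parts.append(compute_delta_amsa(zip(grp["shock_index"], grp["amsa"])))
    frame["psi"] = np.concatenate(psi_parts) if psi_parts else np.array([], dtype=int)
    frame["delta_amsa"] = (
        np.concatenate(delta_parts) if delta_parts else np.array([], dtype=float)
    )
    return frame
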