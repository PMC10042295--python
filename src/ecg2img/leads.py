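"""Augmented-lead derivation and four-lead panel selection.

The imaging pipeline uses a fixed ordered panel of four leads — II, V3,
V5, aVR — chosen from the standard 12-lead set. aVR is an augmented limb
lead: it is not measured independently but computed arithmetically from
the Einthoven limb leads I and II,

    aVR(t) = -(I(t) + II(t)) / 2.

If a record already carries an aVR channel (ECG carts display it by
performing this arithmetic on-device), it is passed through unchanged;
otherwise it is derived from I and II.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, MissingLeadError, ShapeError
from .signal_io import WaveformRecord

#: Fixed top-to-bottom lead order of the imaging panel.
PANEL_ORDER = ("II", "V3", "V5", "aVR")


@dataclass(frozen=True)
class LeadPanel:
    """Ordered four-lead subset of one patient's ECG, ready for imaging."""

    patient_id: str
    leads_in_order: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]
    sampling_rate_hz: float
    label: int | None = None

    def __post_init__(self) -> None:
        if len(self.leads_in_order) != len(PANEL_ORDER):
            raise ShapeError(
                f"panel needs exactly {len(PANEL_ORDER)} leads, "
                f"got {len(self.leads_in_order)}")
        lengths = {np.asarray(x).shape[0] for x in self.leads_in_order}
        if len(lengths) != 1:
            raise ShapeError(f"panel leads have unequal lengths {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return np.asarray(self.leads_in_order[0]).shape[0]

    def lead(self, name: str) -> np.ndarray:
        return self.leads_in_order[PANEL_ORDER.index(name)]


def derive_avr(lead_I: np.ndarray, lead_II: np.ndarray) -> np.ndarray:
    """Compute aVR(t) = -((I(t) + II(t)) / 2) element-wise.

    The formula is symmetric in its two arguments and linear in amplitude.

    Raises
    ------
    EmptyInputError
        If the inputs are empty.
    ShapeError
        If the two leads have different lengths.
    """
    a = np.asarray(lead_I, dtype=np.float64)
    b = np.asarray(lead_II, dtype=np.float64)
    if a.shape != b.shape:
        raise ShapeError(f"lead length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise EmptyInputError("cannot derive aVR from empty leads")
    return -(a + b) / 2.0


def select_panel(record: WaveformRecord) -> LeadPanel:
    """Assemble the ordered (II, V3, V5, aVR) panel from a record.

    aVR is taken from the record when present and derived from I and II
    otherwise.

    Raises
    ------
    MissingLeadError
        Naming the first lead that is absent with no derivation path.
    """
    leads = record.leads
    ordered: list[np.ndarray] = []
    for name in PANEL_ORDER:
        if name in leads:
            ordered.append(leads[name])
        elif name == "aVR" and "I" in leads and "II" in leads:
            ordered.append(derive_avr(leads["I"], leads["II"]))
        else:
            raise MissingLeadError(
                f"record {record.patient_id!r} is missing lead {name}"
                + (" (and I/II for derivation)" if name == "aVR" else ""))
    return LeadPanel(patient_id=record.patient_id,
                     leads_in_order=tuple(ordered),
                     sampling_rate_hz=record.sampling_rate_hz,
                     label=record.label)
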