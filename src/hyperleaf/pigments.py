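"""Reference pigment chemistry from spectrophotometric absorbances.

Leaf pigments extracted in 95% ethanol are quantified from absorbances at
665, 649 and 470 nm with the classic Arnon-type linear system:

    Ca  = 13.95*A665 - 6.88*A649
    Cb  = 24.96*A649 - 7.32*A665
    Cxc = (1000*A470 - 2.05*Ca - 114.8*Cb) / 245
    C   = Ca + Cb

where Ca/Cb are chlorophyll a/b, Cxc carotenoid and C total chlorophyll.
The equations yield solution concentrations; conversion to leaf-area units
(mg/m^2) requires the extract volume and the leaf area, supplied as an
explicit scale factor by the caller.

Negative computed pigments (possible for physically inconsistent
absorbance triples) are returned as computed but flagged, never clamped:
clamping would silently bias downstream model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

# coefficient matrix of the (A665, A649) -> (Ca, Cb) linear map
ARNON_AB = np.array([[13.95, -6.88], [-7.32, 24.96]])
CAROT_CA = 2.05
CAROT_CB = 114.8
CAROT_DEN = 245.0


@dataclass
class PigmentRecord:
    """Absorbances and derived pigment contents for one sample."""

    sample_id: str
    a665: float
    a649: float
    a470: float
    ca: float
    cb: float
    cxc: float
    c: float
    flagged: bool = False  # True when any computed pigment is negative

    def scaled(self, factor: float) -> "PigmentRecord":
        """Apply a volume/area factor converting concentration to mg/m^2."""
        return PigmentRecord(
            self.sample_id,
            self.a665,
            self.a649,
            self.a470,
            self.ca * factor,
            self.cb * factor,
            self.cxc * factor,
            self.c * factor,
            self.flagged,
        )


def arnon_pigments(
    a665: float, a649: float, a470: float, sample_id: str = "", scale: float = 1.0
) -> PigmentRecord:
    """Pigment contents from the three absorbances.

    ``scale`` is an optional pass-through factor (extract volume / leaf
    area) converting solution concentration to per-area content.
    """
    vals = np.array([a665, a649, a470], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("absorbances must be finite")
    ca = 13.95 * a665 - 6.88 * a649
    cb = 24.96 * a649 - 7.32 * a665
    cxc = (1000.0 * a470 - CAROT_CA * ca - CAROT_CB * cb) / CAROT_DEN
    c = ca + cb
    flagged = bool(min(ca, cb, cxc) < 0)
    if flagged:
        log.warning(
            "negative pigment computed for sample %r (Ca=%.4g Cb=%.4g Cxc=%.4g)",
            sample_id,
            ca,
            cb,
            cxc,
        )
    rec = PigmentRecord(sample_id, a665, a649, a470, ca, cb, cxc, c, flagged)
    return rec if scale == 1.0 else rec.scaled(scale)


PIGMENT_COLUMNS = ["sample_id", "A470", "A649", "A665", "Ca", "Cb", "Cxc", "C"]


def records_to_frame(records: list[PigmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "A470": [r.a470 for r in records],
            "A649": [r.a649 for r in records],
            "A665": [r.a665 for r in records],
            "Ca": [r.ca for r in records],
            "Cb": [r.cb for r in records],
            "Cxc": [r.cxc for r in records],
            "C": [r.c for r in records],
        }
    )


def write_pigment_table(records: list[PigmentRecord], path: str, sep: str = "\t") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_pigment_table(path: str, sep: str = "\t", scale: float = 1.0) -> list[PigmentRecord]:
    """Read a delimited absorbance/pigment table.

    When the pigment columns (Ca, Cb, Cxc, C) are absent they are derived
    from the absorbances via :func:`arnon_pigments`.
    """
    df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        if {"Ca", "Cb", "Cxc", "C"}.issubset(df.columns):
            rec = PigmentRecord(
                str(row.get("sample_id", "")),
                float(row["A665"]),
                float(row["A649"]),
                float(row["A470"]),
                float(row["Ca"]),
                float(row["Cb"]),
                float(row["Cxc"]),
                float(row["C"]),
                flagged=bool(min(row["Ca"], row["Cb"], row["Cxc"]) < 0),
            )
        else:
            rec = arnon_pigments(
                float(row["A665"]),
                float(row["A649"]),
                float(row["A470"]),
                sample_id=str(row.get("sample_id", "")),
                scale=scale,
            )
        records.append(rec)
    return records
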