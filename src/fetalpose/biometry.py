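"""Gestational-age-indexed reference anatomy.

Every size threshold in the pipeline is driven by three reference diameters
at the fetal age under examination: the occipitofrontal diameter (OFD),
biparietal diameter (BPD) and ocular diameter (OD), all in mm. The bundled
default table is a synthetic stand-in built from smooth monotone growth
curves anchored at OD(31 wk) = 14 mm and OFD(31 wk) = 96 mm; exact published
norms can be supplied as a TSV override with columns
``ga_weeks  ofd_mm  bpd_mm  od_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

GA_MIN, GA_MAX = 14.0, 40.0


class GestationalAgeError(ValueError):
    """Gestational age outside the supported 14-40 week window."""


@dataclass
class BiometryTable:
    """Rows of (ga_weeks, OFD, BPD, OD), linearly interpolated on lookup."""

    ga_weeks: np.ndarray
    ofd_mm: np.ndarray
    bpd_mm: np.ndarray
    od_mm: np.ndarray

    def __post_init__(self):
        self.ga_weeks = np.asarray(self.ga_weeks, dtype=float)
        self.ofd_mm = np.asarray(self.ofd_mm, dtype=float)
        self.bpd_mm = np.asarray(self.bpd_mm, dtype=float)
        self.od_mm = np.asarray(self.od_mm, dtype=float)
        if not (np.all(np.diff(self.ga_weeks) > 0)):
            raise ValueError("ga_weeks must be strictly increasing")
        if self.ga_weeks[0] > GA_MIN or self.ga_weeks[-1] < GA_MAX:
            raise ValueError(
                f"table must cover gestational ages [{GA_MIN}, {GA_MAX}] weeks"
            )
        for name in ("ofd_mm", "bpd_mm", "od_mm"):
            col = getattr(self, name)
            if np.any(np.diff(col) < 0):
                raise ValueError(f"{name} must be non-decreasing in ga")
        if not np.all((self.ofd_mm > self.bpd_mm) & (self.bpd_mm > self.od_mm)
                      & (self.od_mm > 0)):
            raise ValueError("require OFD > BPD > OD > 0 in every row")

    def lookup(self, ga: float) -> tuple[float, float, float]:
        """(OFD, BPD, OD) in mm at gestational age ``ga`` (weeks)."""
        if not (GA_MIN <= ga <= GA_MAX):
            raise GestationalAgeError(
                f"gestational age {ga} weeks outside supported window "
                f"[{GA_MIN:g}, {GA_MAX:g}]"
            )
        return (
            float(np.interp(ga, self.ga_weeks, self.ofd_mm)),
            float(np.interp(ga, self.ga_weeks, self.bpd_mm)),
            float(np.interp(ga, self.ga_weeks, self.od_mm)),
        )


def load_biometry(path=None) -> BiometryTable:
    """Load a biometry TSV; defaults to the bundled reference table."""
    if path is None:
        ref = resources.files("fetalpose").joinpath("data/biometry_default.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"ga_weeks", "ofd_mm", "bpd_mm", "od_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"biometry table missing columns: {sorted(missing)}")
    return BiometryTable(df["ga_weeks"].to_numpy(), df["ofd_mm"].to_numpy(),
                         df["bpd_mm"].to_numpy(), df["od_mm"].to_numpy())


def lookup(table: BiometryTable, ga: float) -> tuple[float, float, float]:
    """Functional wrapper around :meth:`BiometryTable.lookup`."""
    return table.lookup(ga)
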