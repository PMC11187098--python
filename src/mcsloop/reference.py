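"""Packaged transcription of the bench study's printed measurements.

The CSV fixtures under ``mcsloop/data`` hold every printed number of the four
dose-response tables plus the waveform-session baselines, in a single long
schema (condition, impella_level, ecmo_rpm, quantity, value, unit, source,
anomaly).  Printed values are never altered: known oddities (the ESV jump to
200 ml at ECMO 2000 rpm, which also breaks the SV identity) carry an anomaly
flag and are excluded from calibration objectives, and the two measurement
sessions' disagreeing baselines are kept under their own source tags.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import List, Optional

import pandas as pd

_FILES = ("baselines.csv", "table1_impella.csv", "table2_ecmo.csv",
          "table3_combo_pressures.csv", "table4_combo_flows.csv")

QUANTITIES = {"total_flow", "q_aorta", "q_iliac", "q_brachio", "p_ao_sys",
              "p_ao_dia", "p_ao_mean", "p_vr_mean", "peak_lvp", "edp",
              "esv", "edv", "sv"}


@dataclass(frozen=True)
class ReferenceRecord:
    condition: str
    impella_level: str
    ecmo_rpm: int
    quantity: str
    value: float
    unit: str
    source: str
    anomaly: bool = False

    @property
    def key(self):
        return (self.condition, self.impella_level, self.ecmo_rpm,
                self.quantity, self.source)


def load_reference_frame() -> pd.DataFrame:
    """All transcribed records as one DataFrame (validated)."""
    frames = []
    pkg = resources.files("mcsloop.data")
    for name in _FILES:
        with (pkg / name).open() as fh:
            frames.append(pd.read_csv(fh))
    df = pd.concat(frames, ignore_index=True)
    df["ecmo_rpm"] = df["ecmo_rpm"].astype(int)
    df["anomaly"] = df["anomaly"].astype(bool)
    _validate(df)
    return df


def load_reference() -> List[ReferenceRecord]:
    df = load_reference_frame()
    return [ReferenceRecord(**row) for row in df.to_dict("records")]


def _validate(df: pd.DataFrame) -> None:
    unknown = set(df["quantity"]) - QUANTITIES
    if unknown:
        raise ValueError(f"unknown quantities in fixtures: {unknown}")
    dup = df.duplicated(["condition", "impella_level", "ecmo_rpm",
                         "quantity", "source"])
    if dup.any():
        raise ValueError("duplicate reference records")
    # shared baseline: every table's devices-off CS cell must agree
    base = df[(df.condition == "cs") & (df.impella_level == "P0")
              & (df.ecmo_rpm == 0) & (df.source != "results_baseline")]
    piv = base.pivot_table(index="quantity", columns="source", values="value")
    spread = piv.max(axis=1) - piv.min(axis=1)
    if (spread > 1e-9).any():
        bad = spread[spread > 1e-9].index.tolist()
        raise ValueError(f"table baselines disagree for {bad}")


def lookup(df: pd.DataFrame, quantity: str, condition: str = "cs",
           impella_level: str = "P0", ecmo_rpm: int = 0,
           source: Optional[str] = None) -> float:
    sel = df[(df.quantity == quantity) & (df.condition == condition)
             & (df.impella_level == impella_level) & (df.ecmo_rpm == ecmo_rpm)]
    if source is not None:
        sel = sel[sel.source == source]
    if len(sel) == 0:
        raise KeyError((quantity, condition, impella_level, ecmo_rpm, source))
    return float(sel["value"].iloc[0])


def consistency_report(df: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Residuals of the printed identities SV = EDV - ESV and
    total = iliac + brachiocephalic, wherever all terms are printed.

    Nonzero residuals are transcription-faithful features of the tables, not
    errors to fix; anomalous rows keep their flag.
    """
    if df is None:
        df = load_reference_frame()
    out = []
    keys = ["condition", "impella_level", "ecmo_rpm", "source"]
    for key, grp in df.groupby(keys):
        g = dict(zip(grp["quantity"], grp["value"]))
        anom = bool(grp["anomaly"].any())
        if {"sv", "edv", "esv"} <= g.keys():
            out.append(dict(zip(keys, key), identity="sv=edv-esv",
                            printed=g["sv"], implied=g["edv"] - g["esv"],
                            residual=g["edv"] - g["esv"] - g["sv"],
                            anomaly=anom))
        if {"total_flow", "q_iliac", "q_brachio"} <= g.keys():
            implied = g["q_iliac"] + g["q_brachio"]
            out.append(dict(zip(keys, key), identity="total=iliac+brachio",
                            printed=g["total_flow"], implied=implied,
                            residual=implied - g["total_flow"], anomaly=anom))
    return pd.DataFrame(out)
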