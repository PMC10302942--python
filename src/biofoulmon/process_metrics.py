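"""Process metrics: organic-carbon mass balance and membrane permeability.

Carbon rate (mg/h) balances organic carbon across the module,

    C˙ = TOC_Ret · V˙_Ret − TOC_Feed · V˙_Feed,

negative while biomass accumulates in the module (attachment phase) and
positive once biofilm sloughs off into the retentate (detachment phase).

Permeability (L m⁻² h⁻¹ bar⁻¹) normalizes permeate flow by membrane area and
net transmembrane pressure,

    Pw = V˙_p / (A · TMP_net).

Both accept scalars or aligned arrays; the time-series wrapper propagates
missing inputs as missing outputs, never as silent zeros.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

Number = Union[float, np.ndarray]

#: input columns expected by :func:`derive_series`
SERIES_COLUMNS = ("time_h", "TOC_Feed", "TOC_Ret", "Vdot_Feed", "Vdot_Ret",
                  "Vdot_p", "TMPnet")


def carbon_rate(
    toc_feed: Number, toc_ret: Number, vdot_feed: Number, vdot_ret: Number
) -> Number:
    """Carbon rate C˙ in mg/h from TOC (mg/L) and flows (L/h)."""
    toc_feed, toc_ret = np.asarray(toc_feed, float), np.asarray(toc_ret, float)
    vdot_feed, vdot_ret = np.asarray(vdot_feed, float), np.asarray(vdot_ret, float)
    if np.any(vdot_feed < 0) or np.any(vdot_ret < 0):
        raise InputError("flow rates must be non-negative")
    out = toc_ret * vdot_ret - toc_feed * vdot_feed
    return float(out) if out.ndim == 0 else out


def permeability(vdot_p: Number, membrane_area: Number, tmp_net: Number) -> Number:
    """Permeability Pw in L/(m²·h·bar).

    Raises for non-positive area or net TMP — the quotient is undefined, and
    a zero TMP reading is an instrument fault rather than infinite flux.
    """
    vdot_p = np.asarray(vdot_p, float)
    membrane_area = np.asarray(membrane_area, float)
    tmp_net = np.asarray(tmp_net, float)
    if np.any(membrane_area <= 0):
        raise ConfigurationError("membrane area must be positive")
    if np.any(tmp_net <= 0):
        raise InputError("TMPnet must be positive where permeability is computed")
    out = vdot_p / (membrane_area * tmp_net)
    return float(out) if out.ndim == 0 else out


def derive_series(
    samples: pd.DataFrame, membrane_area: Optional[float] = None
) -> pd.DataFrame:
    """Element-wise carbon rate and permeability over a process table.

    ``samples`` must be sorted by ``time_h`` and carry the columns in
    :data:`SERIES_COLUMNS`; the membrane area comes from a ``membrane_area``
    column or the argument (the flat module's area is not a published
    constant — it is required user input). Rows with missing or invalid
    inputs yield NaN for the affected metric. ``FCP`` is passed through when
    present.
    """
    missing = set(SERIES_COLUMNS) - set(samples.columns)
    if missing:
        raise InputError(f"missing process column(s): {sorted(missing)}")
    t = samples["time_h"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        i = int(np.argmax(np.diff(t) < 0)) + 1
        raise InputError(f"process samples not time-sorted at row {i} (t={t[i]})")

    if "membrane_area" in samples.columns:
        area = samples["membrane_area"].to_numpy(float)
    elif membrane_area is not None:
        area = np.full(len(samples), float(membrane_area))
    else:
        raise ConfigurationError(
            "membrane area required (column 'membrane_area' or argument)"
        )

    toc_feed = samples["TOC_Feed"].to_numpy(float)
    toc_ret = samples["TOC_Ret"].to_numpy(float)
    vdot_feed = samples["Vdot_Feed"].to_numpy(float)
    vdot_ret = samples["Vdot_Ret"].to_numpy(float)
    vdot_p = samples["Vdot_p"].to_numpy(float)
    tmp_net = samples["TMPnet"].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        c_rate = toc_ret * vdot_ret - toc_feed * vdot_feed
        c_rate = np.where(
            (vdot_feed < 0) | (vdot_ret < 0), np.nan, c_rate
        )
        pw = np.where(
            (area > 0) & (tmp_net > 0), vdot_p / (area * tmp_net), np.nan
        )

    out = pd.DataFrame(
        {"time_h": t, "carbon_rate": c_rate, "permeability": pw}
    )
    if "FCP" in samples.columns:
        out["FCP"] = samples["FCP"].to_numpy(float)
    return out
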