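"""Lignin side-chain oxidation marker from pyrolysis-GC/MS peak areas.

The degree of lignin side-chain oxidation is tracked by the peak-area
ratio of 4-acetylguaiacol (oxidized side chain, "Ox-G") to
trans-propenylguaiacol (intact C3 side chain, "C3-G"). The raw ratio
is corrected for the total organic carbon of the extract and normalized
to an uninoculated control extract, which therefore maps to 1.0 by
construction:

    value = (Ox/C3)_sample / (TOC_sample / TOC_control) / (Ox/C3)_control

The TOC correction divides by the relative TOC by default; a multiply
convention is available behind ``toc_correction``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import UndefinedRatioError

__all__ = ["ox_c3g", "ox_c3g_table"]


def _raw_ratio(ox_g: float, c3_g: float) -> float:
    if c3_g <= 0:
        raise UndefinedRatioError("trans-propenylguaiacol (C3-G) area must be positive")
    if ox_g < 0:
        raise UndefinedRatioError("4-acetylguaiacol (Ox-G) area must be non-negative")
    return ox_g / c3_g


def ox_c3g(
    sample_ox_g: float,
    sample_c3_g: float,
    sample_toc: float,
    control_ox_g: float,
    control_c3_g: float,
    control_toc: float,
    toc_correction: str = "divide",
) -> float:
    """TOC-corrected, control-normalized Ox/C3-G ratio for one sample.

    A sample identical to the control returns exactly 1.0. The value is
    invariant to rescaling both marker areas of a sample by a common
    factor, strictly increasing in Ox-G and strictly decreasing in C3-G.
    """
    if sample_toc <= 0 or control_toc <= 0:
        raise UndefinedRatioError("total organic C must be positive")
    if toc_correction not in ("divide", "multiply"):
        raise ValueError("toc_correction must be 'divide' or 'multiply'")
    raw = _raw_ratio(sample_ox_g, sample_c3_g)
    raw_control = _raw_ratio(control_ox_g, control_c3_g)
    if raw_control == 0:
        raise UndefinedRatioError("control Ox/C3-G ratio is zero; normalization undefined")
    rel_toc = sample_toc / control_toc
    corrected = raw / rel_toc if toc_correction == "divide" else raw * rel_toc
    return corrected / raw_control


def ox_c3g_table(
    markers: pd.DataFrame,
    control_id: str | None = None,
    toc_correction: str = "divide",
) -> pd.DataFrame:
    """Vectorized marker normalization over a marker table.

    ``markers`` needs columns ``ox_g``, ``c3_g``, ``toc`` and either a
    boolean ``control`` column or a ``control_id`` matching index labels.
    Control rows are averaged (mean of replicate areas and TOC) before
    normalization. Returns the input plus raw and normalized ratio
    columns.
    """
    required = {"ox_g", "c3_g", "toc"}
    missing = required - set(markers.columns)
    if missing:
        raise ValueError(f"marker table missing columns: {sorted(missing)}")
    if control_id is not None:
        is_control = markers.index == control_id
    elif "control" in markers.columns:
        is_control = markers["control"].astype(bool).to_numpy()
    else:
        raise ValueError("need a 'control' column or a control_id")
    if not is_control.any():
        raise ValueError("no control rows found")
    ctrl = markers.loc[is_control, ["ox_g", "c3_g", "toc"]].mean()

    out = markers.copy()
    out["raw_ratio"] = [
        _raw_ratio(o, c) for o, c in zip(markers["ox_g"], markers["c3_g"])]
    out["ox_c3g"] = [
        ox_c3g(o, c, t, ctrl["ox_g"], ctrl["c3_g"], ctrl["toc"],
               toc_correction=toc_correction)
        for o, c, t in zip(markers["ox_g"], markers["c3_g"], markers["toc"])]
    if np.any(~np.isfinite(out["ox_c3g"].to_numpy(dtype=float))):
        raise UndefinedRatioError("non-finite normalized ratio produced")
    return out
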