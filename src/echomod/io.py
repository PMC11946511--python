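"""Configuration and file I/O.

Config files are YAML with units spelled out in the key names
(``tau_ns``, ``B0_gauss``, ``A_iso_MHz`` ...) to prevent unit bugs.
Unknown keys are rejected.  Time traces travel as two-column ASCII (1D)
or matrix CSV with axis sidecar files (2D); a minimal read/write
implementation of the Bruker BES3T container (.DSC descriptor +
big-endian float64 .DTA) covers 1D and 2D real data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as _dfield
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .eseem import PulseTiming3p, TimeTrace1D
from .hyscore import PulseTiming4p, TimeTrace2D
from .spin import (
    FieldConditions,
    HyperfineCoupling,
    NucleusSpec,
    Quadrupole,
    SpinSystem,
    nucleus,
)


class ConfigError(ValueError):
    """Raised with a list of schema violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid config:\n" + "\n".join(f"  - {v}" for v in self.violations))


class TraceParseError(ValueError):
    pass


@dataclass
class RunConfig:
    system: SpinSystem
    field: FieldConditions
    timing_3p: PulseTiming3p = _dfield(default_factory=PulseTiming3p)
    timing_4p: PulseTiming4p = _dfield(default_factory=PulseTiming4p)
    processing: dict = _dfield(default_factory=dict)
    seed: int = 0
    output_dir: Optional[str] = None


_TOP_KEYS = {"field", "system", "timing_3p", "timing_4p", "processing", "seed", "output_dir"}
_FIELD_KEYS = {"B0_gauss", "mw_freq_GHz"}
_SYSTEM_KEYS = {"g_iso", "nuclei"}
_NUC_KEYS = {"isotope", "count", "A_iso_MHz", "T_dip_MHz", "euler_deg", "quadrupole"}
_QUAD_KEYS = {"K_MHz", "eta", "euler_deg"}
_T3_KEYS = {"tau_ns", "T_start_ns", "dT_ns", "n_points"}
_T4_KEYS = {"tau_ns", "t_start_ns", "dt_ns", "n1", "n2"}
_PROC_KEYS = {"window", "zerofill_1d", "zerofill_2d", "background"}


def _check_keys(d: dict, allowed: set, where: str, bad: list) -> None:
    for k in d:
        if k not in allowed:
            bad.append(f"unknown key {where}.{k}")


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and validate a YAML run configuration.

    All schema violations are collected and reported together in a
    :class:`ConfigError`.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    bad: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a mapping"])
    _check_keys(raw, _TOP_KEYS, "<top>", bad)

    fld = raw.get("field")
    field = None
    if not isinstance(fld, dict):
        bad.append("missing section field")
    else:
        _check_keys(fld, _FIELD_KEYS, "field", bad)
        if "B0_gauss" not in fld:
            bad.append("missing required key field.B0_gauss")
        else:
            try:
                field = FieldConditions(
                    b0_gauss=float(fld["B0_gauss"]),
                    mw_freq_GHz=float(fld.get("mw_freq_GHz", 9.7)),
                )
            except (TypeError, ValueError) as exc:
                bad.append(f"field: {exc}")

    sysd = raw.get("system")
    system = None
    if not isinstance(sysd, dict):
        bad.append("missing section system")
    else:
        _check_keys(sysd, _SYSTEM_KEYS, "system", bad)
        entries = []
        nuclei_raw = sysd.get("nuclei", [])
        if not isinstance(nuclei_raw, list):
            bad.append("system.nuclei must be a list")
            nuclei_raw = []
        for i, nd in enumerate(nuclei_raw):
            where = f"system.nuclei[{i}]"
            if not isinstance(nd, dict):
                bad.append(f"{where} must be a mapping")
                continue
            _check_keys(nd, _NUC_KEYS, where, bad)
            if "isotope" not in nd:
                bad.append(f"missing required key {where}.isotope")
                continue
            try:
                nuc = nucleus(str(nd["isotope"]), count=int(nd.get("count", 1)))
                euler = tuple(
                    math.radians(a) for a in nd.get("euler_deg", (0, 0, 0))
                )
                hf = HyperfineCoupling(
                    a_iso_MHz=float(nd.get("A_iso_MHz", 0.0)),
                    t_dip_MHz=float(nd.get("T_dip_MHz", 0.0)),
                    euler_rad=euler,
                )
                quad = None
                qd = nd.get("quadrupole")
                if qd is not None:
                    _check_keys(qd, _QUAD_KEYS, f"{where}.quadrupole", bad)
                    quad = Quadrupole(
                        K_MHz=float(qd.get("K_MHz", 0.0)),
                        eta=float(qd.get("eta", 0.0)),
                        euler_rad=tuple(
                            math.radians(a) for a in qd.get("euler_deg", (0, 0, 0))
                        ),
                    )
                entries.append(NucleusSpec(nuc, hf, quad))
            except (TypeError, ValueError) as exc:
                bad.append(f"{where}: {exc}")
        if not bad:
            system = SpinSystem(
                nuclei=tuple(entries), g_iso=float(sysd.get("g_iso", 2.0))
            )

    t3 = raw.get("timing_3p", {})
    t4 = raw.get("timing_4p", {})
    _check_keys(t3, _T3_KEYS, "timing_3p", bad)
    _check_keys(t4, _T4_KEYS, "timing_4p", bad)
    proc = raw.get("processing", {})
    _check_keys(proc, _PROC_KEYS, "processing", bad)

    if bad:
        raise ConfigError(bad)

    timing_3p = PulseTiming3p(
        tau=float(t3.get("tau_ns", 210.0)),
        T_start=float(t3.get("T_start_ns", 12.0)),
        dT=float(t3.get("dT_ns", 16.0)),
        n_points=int(t3.get("n_points", 602)),
    )
    timing_4p = PulseTiming4p(
        tau=float(t4.get("tau_ns", 210.0)),
        t_start=float(t4.get("t_start_ns", 40.0)),
        dt=float(t4.get("dt_ns", 32.0)),
        n1=int(t4.get("n1", 256)),
        n2=int(t4.get("n2", 256)),
    )
    return RunConfig(
        system=system,
        field=field,
        timing_3p=timing_3p,
        timing_4p=timing_4p,
        processing=dict(proc),
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir"),
    )


# ---------------------------------------------------------------------------
# ASCII / CSV traces
# ---------------------------------------------------------------------------

def write_trace(trace: Union[TimeTrace1D, TimeTrace2D], path: Union[str, Path]) -> None:
    """Two-column ASCII (1D: ns, amplitude) or matrix CSV + axis sidecars (2D)."""
    path = Path(path)
    if isinstance(trace, TimeTrace1D):
        np.savetxt(path, np.column_stack([trace.t_axis, trace.values]),
                   header="t_ns amplitude", fmt="%.10g")
    else:
        np.savetxt(path, trace.values, delimiter=",", fmt="%.10g")
        np.savetxt(path.with_suffix(path.suffix + ".t1"), trace.t1_axis, fmt="%.10g")
        np.savetxt(path.with_suffix(path.suffix + ".t2"), trace.t2_axis, fmt="%.10g")


def read_trace(path: Union[str, Path], format: str = "ascii"):
    """Read a time trace; ``format`` is ``ascii``, ``csv`` (2D) or ``bes3t``."""
    path = Path(path)
    if format == "bes3t":
        return read_bes3t(path)
    if format == "ascii":
        data = np.loadtxt(path)
        if data.ndim != 2 or data.shape[1] < 2:
            raise TraceParseError(f"{path}: expected two columns (t_ns, amplitude)")
        return TimeTrace1D(data[:, 0], data[:, 1], {"source": str(path)})
    if format == "csv":
        vals = np.loadtxt(path, delimiter=",")
        t1p = path.with_suffix(path.suffix + ".t1")
        t2p = path.with_suffix(path.suffix + ".t2")
        if t1p.exists() and t2p.exists():
            t1 = np.loadtxt(t1p)
            t2 = np.loadtxt(t2p)
        else:
            t1 = np.arange(vals.shape[0], dtype=float)
            t2 = np.arange(vals.shape[1], dtype=float)
        return TimeTrace2D(t1, t2, vals, {"source": str(path)})
    raise ValueError(f"unknown trace format {format!r}")


# ---------------------------------------------------------------------------
# Minimal Bruker BES3T
# ---------------------------------------------------------------------------

_UNIT_TO_NS = {"ns": 1.0, "us": 1e3, "ms": 1e6, "s": 1e9}


def _parse_dsc(path: Path) -> dict:
    """Parse the descriptor into a flat key -> string dict.

    Raises :class:`TraceParseError` with the offending line number for
    lines that are neither comments, section markers, nor key/value
    pairs.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("*", "#", ";")):
                continue
            parts = s.split(None, 1)
            if len(parts) == 1:
                raise TraceParseError(f"{path}:{ln}: malformed descriptor line {s!r}")
            out[parts[0]] = parts[1].strip().strip("'")
    return out


def read_bes3t(path: Union[str, Path]):
    """Read a minimal BES3T pair (.DSC/.DTA), 1D or 2D real data.

    Honors XPTS/XMIN/XWID (and YPTS/YMIN/YWID), BSEQ byte order, and
    IRFMT D (float64).  Axis units are normalized to ns.
    """
    path = Path(path)
    dsc = path.with_suffix(".DSC") if path.suffix.upper() != ".DSC" else path
    dta = dsc.with_suffix(".DTA")
    if not dsc.exists():
        raise FileNotFoundError(dsc)
    meta = _parse_dsc(dsc)
    for key in ("XPTS", "XMIN", "XWID"):
        if key not in meta:
            raise TraceParseError(f"{dsc}: missing required descriptor key {key}")
    if meta.get("IKKF", "REAL").upper() not in ("REAL",):
        raise TraceParseError(f"{dsc}: only IKKF REAL supported, got {meta['IKKF']}")
    fmt = meta.get("IRFMT", "D").upper()
    if fmt != "D":
        raise TraceParseError(f"{dsc}: only IRFMT D (float64) supported, got {fmt}")
    order = ">" if meta.get("BSEQ", "BIG").upper() == "BIG" else "<"
    xpts = int(meta["XPTS"])
    xmin = float(meta["XMIN"])
    xwid = float(meta["XWID"])
    xunit = _UNIT_TO_NS.get(meta.get("XUNI", "ns").lower(), 1.0)
    x = (xmin + xwid * np.arange(xpts) / max(xpts - 1, 1)) * xunit

    data = np.fromfile(dta, dtype=np.dtype(order + "f8"))
    if "YPTS" in meta and int(meta["YPTS"]) > 1:
        ypts = int(meta["YPTS"])
        if data.size != xpts * ypts:
            raise TraceParseError(
                f"{dta}: expected {xpts * ypts} float64 values, found {data.size}"
            )
        ymin = float(meta.get("YMIN", 0.0))
        ywid = float(meta.get("YWID", float(ypts - 1)))
        yunit = _UNIT_TO_NS.get(meta.get("YUNI", "ns").lower(), 1.0)
        y = (ymin + ywid * np.arange(ypts) / max(ypts - 1, 1)) * yunit
        return TimeTrace2D(y, x, data.reshape(ypts, xpts), {"source": str(dta)})
    if data.size != xpts:
        raise TraceParseError(f"{dta}: expected {xpts} float64 values, found {data.size}")
    return TimeTrace1D(x, data, {"source": str(dta)})


def write_bes3t(trace, stem: Union[str, Path]) -> None:
    """Write a minimal BES3T pair for round-trip testing and interchange."""
    stem = Path(stem)
    dsc = stem.with_suffix(".DSC")
    dta = stem.with_suffix(".DTA")
    lines = [
        "#DESC\t1.2 * DESCRIPTOR INFORMATION ***********************",
        "DSRC\tEXP",
        "BSEQ\tBIG",
        "IKKF\tREAL",
        "XTYP\tIDX",
        "IRFMT\tD",
    ]
    if isinstance(trace, TimeTrace1D):
        x = trace.t_axis
        vals = trace.values
        lines += [
            f"XPTS\t{len(x)}",
            f"XMIN\t{x[0]:.10g}",
            f"XWID\t{x[-1] - x[0]:.10g}",
            "XUNI\t'ns'",
            "YTYP\tNODATA",
        ]
    else:
        x = trace.t2_axis
        y = trace.t1_axis
        vals = trace.values
        lines += [
            f"XPTS\t{len(x)}",
            f"XMIN\t{x[0]:.10g}",
            f"XWID\t{x[-1] - x[0]:.10g}",
            "XUNI\t'ns'",
            "YTYP\tIDX",
            f"YPTS\t{len(y)}",
            f"YMIN\t{y[0]:.10g}",
            f"YWID\t{y[-1] - y[0]:.10g}",
            "YUNI\t'ns'",
        ]
    dsc.write_text("\n".join(lines) + "\n")
    np.asarray(vals, dtype=">f8").tofile(dta)


# ---------------------------------------------------------------------------
# Spectra / peaks serialization
# ---------------------------------------------------------------------------

def write_spectrum(spec, path: Union[str, Path]) -> None:
    from .processing import Spectrum1D

    path = Path(path)
    if isinstance(spec, Spectrum1D):
        np.savetxt(path, np.column_stack([spec.freq_MHz, spec.magnitude]),
                   header="freq_MHz magnitude", fmt="%.10g")
    else:
        np.savetxt(path, spec.magnitude, delimiter=",", fmt="%.10g")
        np.savetxt(path.with_suffix(path.suffix + ".f1"), spec.f1_MHz, fmt="%.10g")
        np.savetxt(path.with_suffix(path.suffix + ".f2"), spec.f2_MHz, fmt="%.10g")


def write_peaks(peaks, path: Union[str, Path]) -> None:
    rows = [
        {"nu1_MHz": p.nu1, "nu2_MHz": p.nu2, "height": p.height, "label": p.label}
        for p in peaks
    ]
    Path(path).write_text(json.dumps(rows, indent=2) + "\n")
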