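"""Input/output layer: run configuration, file readers and the JSON results store.

All external formats touched by the pipeline pass through this module:

* 1-D scattering curves as whitespace-delimited ASCII (``q  I  [sigma_I]``,
  ``#`` comments),
* calorimetry scans as two-column CSV (``temperature,cp``),
* two-channel fluorescence stacks as multi-page TIFF,
* analysis results as versioned JSON documents.

Internal units are fixed here once and for all: scattering vectors in
inverse ångström, temperatures in kelvin.  Readers normalise at the
boundary so that downstream modules never see raw instrument units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("membranalysis")

SCHEMA_VERSION = 1

#: gas constant in cal mol^-1 K^-1 — the unit that makes the van't Hoff
#: expression 4*R*Tm^2/T_half come out in cal/mol alongside kcal/mol tables.
GAS_CONSTANT_CAL = 1.9872

CELSIUS_OFFSET = 273.15


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    """Run-wide settings shared by the CLI and the library entry points.

    Parameters
    ----------
    q_units:
        Unit of the scattering vector in input files, ``"inverse_angstrom"``
        or ``"inverse_nanometer"``.  Internally q is always Å⁻¹.
    channel_order:
        Page interleaving of two-channel TIFF stacks; ``"blue_first"`` means
        even pages are the 440 nm band.
    temperature_units:
        ``"celsius"`` or ``"kelvin"`` for thermogram files.
    gas_constant:
        R in cal mol⁻¹ K⁻¹ (must be positive).
    reference_gp:
        Generalized polarization of the calibration standard (laurdan in
        DMSO), strictly inside (−1, 1).  No default exists in hardware; the
        conventional literature value 0.207 is used unless overridden.
    random_seed:
        Seed for every stochastic step of a run.
    """

    q_units: str = "inverse_angstrom"
    channel_order: str = "blue_first"
    temperature_units: str = "celsius"
    gas_constant: float = GAS_CONSTANT_CAL
    reference_gp: float = 0.207
    random_seed: int = 0
    logging_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.q_units not in ("inverse_angstrom", "inverse_nanometer"):
            raise ValueError(f"unknown q_units {self.q_units!r}")
        if self.channel_order not in ("blue_first", "red_first"):
            raise ValueError(f"unknown channel_order {self.channel_order!r}")
        if self.temperature_units not in ("celsius", "kelvin"):
            raise ValueError(f"unknown temperature_units {self.temperature_units!r}")
        if not self.gas_constant > 0:
            raise ValueError("gas_constant must be positive")
        if not -1.0 < self.reference_gp < 1.0:
            raise ValueError("reference_gp must lie strictly inside (-1, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# unit helpers (exact inverses by construction)


def nm_inv_to_angstrom_inv(q_nm: np.ndarray | float) -> np.ndarray | float:
    """1 nm⁻¹ = 0.1 Å⁻¹."""
    return np.multiply(q_nm, 0.1)


def angstrom_inv_to_nm_inv(q_a: np.ndarray | float) -> np.ndarray | float:
    return np.multiply(q_a, 10.0)


def celsius_to_kelvin(t_c: np.ndarray | float) -> np.ndarray | float:
    return np.add(t_c, CELSIUS_OFFSET)


def kelvin_to_celsius(t_k: np.ndarray | float) -> np.ndarray | float:
    return np.subtract(t_k, CELSIUS_OFFSET)


# ---------------------------------------------------------------------------
# domain containers


@dataclass
class ScatteringCurve:
    """A 1-D scattering profile I(q) with per-point uncertainties.

    q is in Å⁻¹ and strictly increasing; intensities are in arbitrary units
    with strictly positive uncertainties.
    """

    q: np.ndarray
    I: np.ndarray
    sigma_I: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma_I = np.asarray(self.sigma_I, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma_I.shape):
            raise ValueError("q, I and sigma_I must have equal lengths")
        if self.q.size and not np.all(self.q > 0):
            raise ValueError("q must be strictly positive")
        if self.q.size > 1 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q must be strictly increasing")
        if self.q.size and not np.all(self.sigma_I > 0):
            raise ValueError("sigma_I must be strictly positive")

    def trim(self, q_min: float | None = None, q_max: float | None = None) -> "ScatteringCurve":
        lo = -np.inf if q_min is None else q_min
        hi = np.inf if q_max is None else q_max
        keep = (self.q >= lo) & (self.q <= hi)
        return ScatteringCurve(self.q[keep], self.I[keep], self.sigma_I[keep])


@dataclass
class Thermogram:
    """A single calorimetry scan: apparent molar heat capacity versus T (K)."""

    T: np.ndarray
    Cp: np.ndarray
    scan_rate: float | None = None  # K/min, metadata only
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.Cp = np.asarray(self.Cp, dtype=float)
        if self.T.shape != self.Cp.shape:
            raise ValueError("T and Cp must have equal lengths")
        if self.T.size > 1 and not np.all(np.diff(self.T) > 0):
            raise ValueError("temperature must be strictly increasing")


@dataclass
class TwoChannelImage:
    """Registered blue/red band frames of one time point.

    I440 is the blue band (438±12 nm), I490 the red band (494±10 nm).
    """

    I440: np.ndarray
    I490: np.ndarray
    timestamp: float = 0.0  # minutes

    def __post_init__(self) -> None:
        self.I440 = np.asarray(self.I440)
        self.I490 = np.asarray(self.I490)
        if self.I440.shape != self.I490.shape:
            raise ValueError("channel frames must have equal shapes")
        if not (np.all(np.isfinite(self.I440)) and np.all(np.isfinite(self.I490))):
            raise ValueError("channel intensities must be finite")
        if np.any(self.I440 < 0) or np.any(self.I490 < 0):
            raise ValueError("channel intensities must be non-negative")


# ---------------------------------------------------------------------------
# readers


def read_scattering_curve(path: str | Path, q_units: str = "inverse_angstrom") -> ScatteringCurve:
    """Read a whitespace-delimited ASCII scattering curve.

    Columns are ``q  I  [sigma_I]``; lines starting with ``#`` are comments.
    q is converted to Å⁻¹ on read.  A missing third column is filled with
    the Poisson-like default ``sqrt(max(I, 1))`` (logged as a warning); rows
    containing non-finite numbers are dropped and counted in the log.
    """
    path = Path(path)
    rows: list[tuple[int, list[float]]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}")
            try:
                vals = [float(x) for x in fields[:3]]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable number ({exc})") from None
            if ncols is None:
                ncols = len(vals)
            rows.append((lineno, vals))

    if not rows:
        raise ValueError(f"{path}: empty scattering file")

    kept_lines = []
    kept = []
    n_dropped = 0
    for lineno, vals in rows:
        if not all(np.isfinite(v) for v in vals):
            n_dropped += 1
            continue
        kept_lines.append(lineno)
        kept.append(vals)
    if n_dropped:
        logger.info("%s: dropped %d rows with non-finite values", path, n_dropped)
    if not kept:
        raise ValueError(f"{path}: no finite rows")

    arr = np.array([v[:2] for v in kept], dtype=float)
    q, I = arr[:, 0], arr[:, 1]
    has_sigma = all(len(v) >= 3 for v in kept)
    if has_sigma:
        sigma = np.array([v[2] for v in kept], dtype=float)
        bad = np.where(sigma < 0)[0]
        if bad.size:
            raise ValueError(f"{path}:{kept_lines[bad[0]]}: negative sigma_I")
        # zero uncertainty is as unusable as negative: fall back per point
        zero = sigma == 0
        if np.any(zero):
            sigma = np.where(zero, np.sqrt(np.maximum(I, 1.0)), sigma)
            logger.warning("%s: %d zero sigma_I replaced by sqrt(max(I,1))", path, int(zero.sum()))
    else:
        logger.warning("%s: no sigma_I column; assuming sqrt(max(I, 1))", path)
        sigma = np.sqrt(np.maximum(I, 1.0))

    dq = np.diff(q)
    bad = np.where(dq <= 0)[0]
    if bad.size:
        raise ValueError(f"{path}:{kept_lines[bad[0] + 1]}: q not strictly increasing")

    if q_units == "inverse_nanometer":
        q = nm_inv_to_angstrom_inv(q)
    elif q_units != "inverse_angstrom":
        raise ValueError(f"unknown q_units {q_units!r}")
    return ScatteringCurve(q=q, I=I, sigma_I=sigma)


def write_scattering_curve(curve: ScatteringCurve, path: str | Path, header: str = "") -> None:
    """Write a curve in the same 3-column ASCII layout the reader accepts."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q[1/A]  I[a.u.]  sigma_I[a.u.]\n")
        for qi, ii, si in zip(curve.q, curve.I, curve.sigma_I):
            fh.write(f"{qi:.8e} {ii:.8e} {si:.8e}\n")


def read_thermogram(
    path: str | Path,
    temperature_units: str = "celsius",
    scan_rate: float | None = None,
) -> Thermogram:
    """Read a two-column CSV thermogram (header ``temperature,cp``).

    Temperatures are stored in kelvin.  Rows are stably sorted by
    temperature and duplicate temperatures are averaged, so the result does
    not depend on row order in the file.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        t_col, cp_col = cols["temperature"], cols["cp"]
    except KeyError:
        raise ValueError(f"{path}: expected CSV header with 'temperature' and 'cp' columns") from None
    df = df[[t_col, cp_col]].dropna()
    if len(df) < 10:
        raise ValueError(f"{path}: scan too short to analyze ({len(df)} rows)")
    T = df[t_col].to_numpy(dtype=float)
    Cp = df[cp_col].to_numpy(dtype=float)
    if temperature_units == "celsius":
        T = celsius_to_kelvin(T)
    elif temperature_units != "kelvin":
        raise ValueError(f"unknown temperature_units {temperature_units!r}")
    grouped = pd.DataFrame({"T": T, "Cp": Cp}).groupby("T", sort=True)["Cp"].mean()
    return Thermogram(T=grouped.index.to_numpy(), Cp=grouped.to_numpy(), scan_rate=scan_rate)


def write_thermogram(tg: Thermogram, path: str | Path, temperature_units: str = "celsius") -> None:
    T = kelvin_to_celsius(tg.T) if temperature_units == "celsius" else tg.T
    pd.DataFrame({"temperature": T, "cp": tg.Cp}).to_csv(path, index=False)


def read_image_stack(path: str | Path, channel_order: str = "blue_first") -> list[TwoChannelImage]:
    """Read a multi-page TIFF into a time series of paired channel frames.

    Pages alternate channels; ``blue_first`` puts the 440 nm band on even
    pages.  Page count must be even and all pages equally sized.
    """
    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2-D pages, got shape {pages.shape}")
    n = pages.shape[0]
    if n % 2:
        raise ValueError(f"{path}: odd page count {n}; channels cannot be paired")
    if channel_order == "blue_first":
        blue, red = pages[0::2], pages[1::2]
    elif channel_order == "red_first":
        red, blue = pages[0::2], pages[1::2]
    else:
        raise ValueError(f"unknown channel_order {channel_order!r}")
    return [
        TwoChannelImage(I440=b, I490=r, timestamp=float(t))
        for t, (b, r) in enumerate(zip(blue, red))
    ]


def write_image_stack(
    frames: Sequence[TwoChannelImage], path: str | Path, channel_order: str = "blue_first"
) -> None:
    pages = []
    for fr in frames:
        pair = (fr.I440, fr.I490) if channel_order == "blue_first" else (fr.I490, fr.I440)
        pages.extend(pair)
    tifffile.imwrite(path, np.stack(pages).astype(np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# results store


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            "data": {
                f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    results,
    path: str | Path,
    config: RunConfig | None = None,
    inputs: Iterable[str | Path] = (),
) -> None:
    """Write any analysis record (or list of records) as a JSON document.

    The document carries a schema version, sha256 checksums of the input
    files, an echo of the run configuration and the full payload; it
    round-trips losslessly through :func:`read_results`.
    """
    doc = {
        "schema_version": SCHEMA_VERSION,
        "input_checksums": {str(p): file_checksum(p) for p in inputs},
        "config": config.to_dict() if config is not None else None,
        "results": _jsonable(results),
    }
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc


def read_results(path: str | Path, registry: dict | None = None):
    """Read a results document; reconstruct dataclasses found in *registry*.

    *registry* maps ``__type__`` names to dataclass constructors.  Unknown
    types are returned as plain dicts.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema version {doc.get('schema_version')}")

    def rebuild(node):
        if isinstance(node, dict) and "__type__" in node:
            data = {k: rebuild(v) for k, v in node["data"].items()}
            cls = (registry or {}).get(node["__type__"])
            return cls(**data) if cls is not None else data
        if isinstance(node, dict):
            return {k: rebuild(v) for k, v in node.items()}
        if isinstance(node, list):
            return [rebuild(v) for v in node]
        return node

    return rebuild(doc["results"])
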