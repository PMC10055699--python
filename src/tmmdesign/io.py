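"""Readers/writers for spectral CSVs, stack YAML, ENVI cubes, PNG masks,
and the per-run reproducibility manifest.

All writers are deterministic given identical inputs (apart from the
manifest's wall-clock timestamp); all readers validate invariants and
fail with actionable, line-numbered messages.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from PIL import Image

from .spectra import SpectralCurve, SpectralGrid
from .synthetic import Scene
from .tmm import LayerStack, SpectralResponse

__all__ = [
    "read_spectral_csv",
    "write_spectral_csv",
    "write_response_csv",
    "read_stack_yaml",
    "write_stack_yaml",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask_png",
    "write_mask_png",
    "RunManifest",
    "file_sha256",
]


# ---------------------------------------------------------------------------
# Spectral curves: CSV with mandatory header (wavelength_nm, value, ...)
# ---------------------------------------------------------------------------


def read_spectral_csv(path: str | Path, column: int = 1) -> SpectralCurve:
    """Read a two-or-more-column spectral CSV; rows are sorted by wavelength.

    Transmittance/response values must be finite and inside [0, 1.5]
    (a little headroom above 1 for raw response curves); violations are
    reported with their line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2:
        raise ValueError(f"{path}: need a header row and at least one data row")
    wl, vals = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            w = float(parts[0])
            v = float(parts[column])
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}") from exc
        if not (np.isfinite(w) and np.isfinite(v)):
            raise ValueError(f"{path}: non-finite value at line {lineno}")
        if not 0.0 <= v <= 1.5:
            raise ValueError(f"{path}: value {v} outside [0, 1.5] at line {lineno}")
        wl.append(w)
        vals.append(v)
    order = np.argsort(wl)
    wl_arr = np.asarray(wl)[order]
    if np.any(np.diff(wl_arr) <= 0):
        dup = int(np.argmax(np.diff(wl_arr) <= 0))
        raise ValueError(f"{path}: duplicate wavelength {wl_arr[dup]:g} nm")
    return SpectralCurve(SpectralGrid(wl_arr), np.asarray(vals)[order], name=path.stem)


def write_spectral_csv(curve: SpectralCurve, path: str | Path, value_name: str = "T") -> None:
    path = Path(path)
    rows = [f"wavelength_nm,{value_name}"]
    rows += [f"{w:.6g},{v:.10g}" for w, v in zip(curve.grid.wavelengths, curve.values)]
    path.write_text("\n".join(rows) + "\n")


def write_response_csv(response: SpectralResponse, path: str | Path) -> None:
    """Full polarized spectrum: wavelength, T_s, T_p, T_unpolarized."""
    path = Path(path)
    rows = ["wavelength_nm,T_s,T_p,T_unpolarized"]
    for w, ts, tp, tu in zip(
        response.grid.wavelengths, response.T_s, response.T_p, response.T_unpolarized
    ):
        rows.append(f"{w:.6g},{ts:.10g},{tp:.10g},{tu:.10g}")
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Layer stacks: YAML {n0, substrate_index, layers: [{index, thickness_nm}]}
# ---------------------------------------------------------------------------


def read_stack_yaml(path: str | Path) -> LayerStack:
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    try:
        n0 = float(data["n0"])
        n_sub = float(data["substrate_index"])
        layers = data["layers"]
        indices = np.array([float(l["index"]) for l in layers])
        thicknesses = np.array([float(l["thickness_nm"]) for l in layers])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"{path}: malformed stack file ({exc})") from exc
    if np.any(thicknesses < 0):
        bad = int(np.argmax(thicknesses < 0))
        raise ValueError(f"{path}: negative thickness in layer {bad + 1}")
    if n0 < 1 or n_sub < 1 or np.any(indices < 1):
        raise ValueError(f"{path}: refractive indices must be ≥ 1")
    return LayerStack(n0, indices, thicknesses, n_sub)


def write_stack_yaml(stack: LayerStack, path: str | Path) -> None:
    data = {
        "n0": float(stack.n0),
        "substrate_index": float(stack.n_sub),
        "layers": [
            {"index": float(n), "thickness_nm": float(d)}
            for n, d in zip(stack.layer_indices, stack.thicknesses)
        ],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# ENVI cubes: text .hdr + band-sequential float32 binary
# ---------------------------------------------------------------------------


def write_envi_cube(scene: Scene, path: str | Path) -> None:
    """Write an ENVI BSQ pair: ``path`` (raw float32) + ``path + '.hdr'``."""
    path = Path(path)
    cube = np.ascontiguousarray(scene.cube.astype("<f4"))
    h, w, bands = cube.shape
    hdr = [
        "ENVI",
        "description = {synthetic scene}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{x:.6g}" for x in scene.band_wavelengths) + "}",
    ]
    Path(str(path) + ".hdr").write_text("\n".join(hdr) + "\n")
    # BSQ: band-major layout
    np.transpose(cube, (2, 0, 1)).tofile(path)


def _parse_envi_header(text: str, path: Path) -> dict:
    fields: dict[str, str] = {}
    key, buf, in_braces = None, "", False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_braces:
            buf += " " + line
            if "}" in line:
                fields[key] = buf
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and "}" not in val:
            buf, in_braces = val, True
        else:
            fields[key] = val
    required = ("samples", "lines", "bands", "data type", "interleave")
    for r in required:
        if r not in fields:
            raise ValueError(f"{path}: ENVI header missing field {r!r}")
    return fields


def read_envi_cube(path: str | Path) -> Scene:
    path = Path(path)
    hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header {hdr_path}")
    fields = _parse_envi_header(hdr_path.read_text(), hdr_path)
    if fields["data type"] != "4" or fields["interleave"].lower() != "bsq":
        raise ValueError(f"{path}: only float32 BSQ cubes are supported")
    w, h, bands = int(fields["samples"]), int(fields["lines"]), int(fields["bands"])
    raw = np.fromfile(path, dtype="<f4")
    if raw.size != w * h * bands:
        raise ValueError(f"{path}: file size does not match header dimensions")
    cube = np.transpose(raw.reshape(bands, h, w), (1, 2, 0)).astype(float)
    wl_field = fields.get("wavelength", "")
    wl = np.array(
        [float(x) for x in wl_field.strip("{} ").split(",") if x.strip()], dtype=float
    )
    if wl.size != bands:
        raise ValueError(f"{path}: header lists {wl.size} wavelengths for {bands} bands")
    mask_path = path.with_suffix(".mask.png")
    mask = read_mask_png(mask_path) if mask_path.exists() else np.zeros((h, w), np.uint8)
    return Scene(cube=cube, band_wavelengths=wl, mask=mask)


# ---------------------------------------------------------------------------
# Masks: 8-bit PNG, 0 = background, 255 = pepper
# ---------------------------------------------------------------------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255).clip(0, 255))
    img.save(Path(path), format="PNG")


def read_mask_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    return (arr >= 128).astype(np.uint8)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-execute a run: command, parameters, seed, hashes."""

    command: str
    parameters: Mapping[str, object]
    master_seed: int
    input_hashes: Mapping[str, str] = field(default_factory=dict)
    tool_version: str = "0.1.0"
    timestamp: float = field(default_factory=time.time)

    def to_json(self, include_timestamp: bool = True) -> str:
        payload = {
            "command": self.command,
            "parameters": dict(self.parameters),
            "master_seed": self.master_seed,
            "input_hashes": dict(self.input_hashes),
            "tool_version": self.tool_version,
        }
        if include_timestamp:
            payload["timestamp"] = self.timestamp
        return json.dumps(payload, sort_keys=True, indent=2, default=str)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
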