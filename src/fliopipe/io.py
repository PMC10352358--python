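"""File formats: HDF5 histogram cubes, TIFF lifetime maps, CSV tables,
TOML configuration and pseudo-color PNG rendering.

The vendor device format (.sdt) is deliberately not parsed; real data
enters through the documented HDF5 cube layout plus a subject covariate
CSV.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import h5py
import matplotlib.image
import numpy as np
import tifffile
from matplotlib.colors import LinearSegmentedColormap

from .decay import DecayHistogramCube
from .errors import ConfigurationError, FormatError
from .fitting import FitConfig, FLTMaps
from .simulate import AcquisitionConfig, PopulationParams, default_population
from .stats import StatsConfig

__all__ = [
    "write_cube", "read_cube", "write_maps", "read_maps",
    "render_pseudocolor", "RunConfig", "load_config", "dump_config",
]

#: Continuous orange -> blue colormap: short lifetimes orange, long blue,
#: the display convention of FLIO pseudo-color images.
FLIO_CMAP = LinearSegmentedColormap.from_list(
    "flio", ["#ff7f00", "#ffd37f", "#ffffff", "#7fb2ff", "#0000ff"]
)


def write_cube(path, cube: DecayHistogramCube) -> None:
    """Write a histogram cube to the shared HDF5 layout.

    Datasets: ``/counts`` (channel, row, col, bin; unsigned int),
    ``/time_axis_ps``, ``/channels``; acquisition metadata as attributes of
    ``/meta``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=cube.counts.astype(np.uint32), compression="gzip")
        f.create_dataset("time_axis_ps", data=cube.time_axis_ps)
        f.create_dataset("channels", data=np.array(cube.channels, dtype=h5py.string_dtype()))
        meta = f.create_group("meta")
        for k, v in cube.meta.items():
            meta.attrs[k] = v


def read_cube(path) -> DecayHistogramCube:
    """Read a cube written by :func:`write_cube`; bit-exact round trip."""
    with h5py.File(path, "r") as f:
        for name in ("counts", "time_axis_ps", "channels"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset /{name}")
        counts = f["counts"][()]
        time_axis = f["time_axis_ps"][()]
        channels = tuple(c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()])
        if counts.ndim != 4:
            raise FormatError(f"{path}: /counts must be 4-D (channel,row,col,bin), got {counts.shape}")
        if counts.shape[-1] != len(time_axis):
            raise FormatError(f"{path}: /counts last axis does not match /time_axis_ps")
        meta = dict(f["meta"].attrs) if "meta" in f else {}
    return DecayHistogramCube(counts=counts.astype(np.int64), time_axis_ps=time_axis,
                              channels=channels, meta=meta)


def write_maps(outdir, maps: FLTMaps, prefix: str = "") -> list[Path]:
    """Write lifetime maps as 32-bit float TIFFs plus an 8-bit validity mask."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tag = f"{prefix}{maps.channel}" if maps.channel else prefix.rstrip("_")
    for name, img in maps.as_dict().items():
        p = outdir / f"{tag}_{name}.tif"
        tifffile.imwrite(p, img.astype(np.float32))
        written.append(p)
    p = outdir / f"{tag}_valid.tif"
    tifffile.imwrite(p, maps.valid.astype(np.uint8))
    written.append(p)
    return written


def read_maps(outdir, channel: str, prefix: str = "") -> FLTMaps:
    """Read back a map set written by :func:`write_maps`."""
    outdir = Path(outdir)
    tag = f"{prefix}{channel}"
    imgs = {}
    for name in ("tau1", "tau2", "alpha1", "alpha2", "tau_m", "chi2_reduced", "intensity"):
        p = outdir / f"{tag}_{name}.tif"
        if not p.exists():
            raise FormatError(f"missing map file {p}")
        imgs[name] = tifffile.imread(p).astype(float)
    valid = tifffile.imread(outdir / f"{tag}_valid.tif").astype(bool)
    return FLTMaps(**imgs, valid=valid, channel=channel)


def render_pseudocolor(map_image, value_range: tuple[float, float], path,
                       mask=None, colorbar: bool = False) -> None:
    """Render a parameter map as a pseudo-color PNG.

    Small values map to orange and large values to blue over
    ``value_range``; out-of-range values are clipped to the extremes;
    masked or non-finite pixels are black.
    """
    img = np.asarray(map_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty map")
    lo, hi = value_range
    if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
        raise ValueError("value_range must be finite with min < max")
    bad = ~np.isfinite(img)
    if mask is not None:
        bad |= ~np.asarray(mask, dtype=bool)
    scaled = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    rgba = FLIO_CMAP(scaled)
    rgba[bad] = (0.0, 0.0, 0.0, 1.0)
    if colorbar:
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots()
        im = ax.imshow(np.ma.masked_array(img, bad), cmap=FLIO_CMAP, vmin=lo, vmax=hi)
        ax.set_axis_off()
        fig.colorbar(im, ax=ax)
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    else:
        matplotlib.image.imsave(path, rgba)


@dataclasses.dataclass
class RunConfig:
    """Complete, TOML-serializable pipeline configuration."""

    acquisition: AcquisitionConfig = dataclasses.field(default_factory=AcquisitionConfig)
    population: PopulationParams = dataclasses.field(default_factory=default_population)
    fit: FitConfig = dataclasses.field(default_factory=FitConfig)
    stats: StatsConfig = dataclasses.field(default_factory=StatsConfig)
    n_nonsmokers: int = 26
    n_smokers: int = 28
    seed: int = 0
    outdir: str = "flio_out"
    log_level: str = "INFO"


_SECTIONS = {
    "acquisition": AcquisitionConfig,
    "fit": FitConfig,
    "stats": StatsConfig,
}
_TOP_KEYS = ("n_nonsmokers", "n_smokers", "seed", "outdir", "log_level")
# Population keys serialized to TOML (the per-region tables keep their
# code defaults; override them programmatically if needed).
_POPULATION_SCALARS = ("tau1_ratio", "tau2_sd", "rho", "group_effects",
                       "pack_year_log_median", "pack_year_log_sigma")


def _coerce(cls, data: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigurationError(f"unknown key '{section}.{key}'")
        f = fields[key]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Parse a TOML run configuration; unknown keys are rejected by name."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _coerce(_SECTIONS[key], value, key)
        elif key == "population":
            bad = set(value) - set(_POPULATION_SCALARS)
            if bad:
                raise ConfigurationError(f"unknown key 'population.{sorted(bad)[0]}'")
            kwargs["population"] = default_population(**value)
        elif key in _TOP_KEYS:
            kwargs[key] = value
        else:
            raise ConfigurationError(f"unknown key '{key}'")
    return RunConfig(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_config(config: RunConfig, path) -> None:
    """Serialize a RunConfig back to TOML (inverse of :func:`load_config`)."""
    lines = []
    for key in _TOP_KEYS:
        lines.append(f"{key} = {_toml_value(getattr(config, key))}")
    for section, cls in _SECTIONS.items():
        lines.append(f"\n[{section}]")
        obj = getattr(config, section if section != "fit" else "fit")
        for f in dataclasses.fields(cls):
            lines.append(f"{f.name} = {_toml_value(getattr(obj, f.name))}")
    lines.append("\n[population]")
    for name in _POPULATION_SCALARS:
        lines.append(f"{name} = {_toml_value(getattr(config.population, name))}")
    Path(path).write_text("\n".join(lines) + "\n")
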