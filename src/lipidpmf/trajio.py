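"""Reading and writing collective-variable time series and run configs.

Two on-disk dialects are supported, both whitespace-delimited text:

* the PLUMED COLVAR dialect — first line ``#! FIELDS time d1 ...`` naming
  the columns, subsequent ``#!``/``#`` lines treated as comments;
* the GROMACS XVG dialect — lines starting with ``#`` or ``@`` ignored,
  columns positional.

Analysis configuration is a YAML mapping with a documented schema (see
``AnalysisConfig.from_file``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .constants import DEFAULT_TEMPERATURE

__all__ = [
    "CVTrajectory",
    "AnalysisConfig",
    "UmbrellaProtocol",
    "read_colvar",
    "write_colvar",
    "read_xvg",
    "write_xvg",
    "apply_burn_in",
    "load_config",
]


@dataclass(frozen=True)
class UmbrellaProtocol:
    """Umbrella-window ladder and exchange protocol.

    Defaults mirror the coarse-grained membrane-binding protocol: 16
    harmonic windows with centres linearly spaced on [0.4, 1.5] nm along
    the protein-lipid minimum distance, force constant
    1000 kJ mol^-1 nm^-2, neighbour-exchange attempts every 1000 steps,
    323 K.  ``window_time_us`` records the per-window physical simulation
    time the protocol emulates (15 us per replica).
    """

    centers: tuple[float, ...] = tuple(np.linspace(0.4, 1.5, 16).round(10))
    force_constant: float = 1000.0  # kJ mol^-1 nm^-2
    exchange_interval: int = 1000  # steps
    temperature: float = DEFAULT_TEMPERATURE  # K
    n_steps: int = 100_000  # sampler steps per window
    burn_in: int = 0  # steps discarded before analysis
    seed: int = 0
    window_time_us: float = 15.0  # emulated physical time per window

    def __post_init__(self):
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or len(c) < 1:
            raise ValueError("centers must be a non-empty 1D sequence")
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("window centers must be strictly increasing")
        if self.force_constant <= 0:
            raise ValueError("force_constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n_windows(self) -> int:
        return len(self.centers)

    def bias_energy(self, xi1, window_index: int) -> np.ndarray:
        """Harmonic bias 0.5*k*(xi1 - c_i)^2 for the given window."""
        c = self.centers[window_index]
        return 0.5 * self.force_constant * (np.asarray(xi1, float) - c) ** 2

    def total_time_us(self) -> float:
        """Aggregate emulated simulation time over all windows (us)."""
        return self.n_windows * self.window_time_us


@dataclass
class CVTrajectory:
    """Per-window (or per-replica) collective-variable time series.

    ``xi1`` is the protein-lipid minimum distance (nm); ``xi2`` the
    protein-membrane COM distance (nm); ``xi3`` the cosine of the helix
    tilt angle, in [-1, 1].  ``window_index`` is either a scalar (series
    recorded in one umbrella window) or a per-frame array (demultiplexed
    replica wandering through window space).
    """

    time: np.ndarray
    xi1: np.ndarray
    xi2: np.ndarray | None = None
    xi3: np.ndarray | None = None
    window_index: int | np.ndarray = 0
    replica_index: np.ndarray | None = None
    source: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.xi1 = np.asarray(self.xi1, dtype=float)
        n = len(self.time)
        if len(self.xi1) != n:
            raise ValueError("time and xi1 must have equal length")
        for name in ("xi2", "xi3", "replica_index"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float if name != "replica_index" else int)
                if len(v) != n:
                    raise ValueError(f"{name} length {len(v)} != {n}")
                setattr(self, name, v)
        if np.any(self.xi1 <= 0):
            raise ValueError("xi1 (a distance) must be strictly positive")
        if self.xi3 is not None and (np.any(self.xi3 < -1) or np.any(self.xi3 > 1)):
            raise ValueError("xi3 (a cosine) must lie in [-1, 1]")

    def __len__(self) -> int:
        return len(self.time)

    def slice(self, mask: np.ndarray) -> "CVTrajectory":
        wi = self.window_index
        if isinstance(wi, np.ndarray):
            wi = wi[mask]
        return CVTrajectory(
            time=self.time[mask],
            xi1=self.xi1[mask],
            xi2=None if self.xi2 is None else self.xi2[mask],
            xi3=None if self.xi3 is None else self.xi3[mask],
            window_index=wi,
            replica_index=None
            if self.replica_index is None else self.replica_index[mask],
            source=self.source,
        )


@dataclass
class AnalysisConfig:
    """Analysis parameters: binning, WHAM convergence, binding geometry.

    YAML schema (all keys optional unless noted)::

        protocol:
          centers: [0.4, ..., 1.5]      # nm; default 16 windows
          force_constant: 1000.0        # kJ/mol/nm^2
          exchange_interval: 1000       # steps
          temperature: 323.0            # K
          n_steps: 100000               # sampler steps per window
          seed: 0
        burn_in_fraction: 0.1333        # fraction of each series discarded
        xi1_bins: {min: 0.35, max: 1.6, width: 0.02}   # nm
        fes_bins: 60                    # per axis for 2D surfaces
        wham_tolerance: 1.0e-7          # kJ/mol on window offsets
        max_iterations: 100000
        plateau_region: [1.4, 1.5]      # nm; PMF zero reference
        binding: {b: 1.0, area_A: 40.0, box_Lz: .inf}  # nm / nm^2; area required
        n_pip3: 3
    """

    protocol: UmbrellaProtocol = field(default_factory=UmbrellaProtocol)
    burn_in_fraction: float = 2.0 / 15.0
    burn_in_time: float | None = None
    xi1_bin_min: float = 0.35
    xi1_bin_max: float = 1.6
    xi1_bin_width: float = 0.02
    fes_bins: int = 60
    wham_tolerance: float = 1e-7
    max_iterations: int = 100_000
    plateau_region: tuple[float, float] = (1.4, 1.5)
    b: float = 1.0  # bound-state cutoff, nm
    area_A: float | None = None  # membrane x-y area, nm^2 (user input)
    box_Lz: float = np.inf  # nm
    n_pip3: int = 1

    def __post_init__(self):
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.xi1_bin_width <= 0 or self.xi1_bin_max <= self.xi1_bin_min:
            raise ValueError("invalid xi1 binning")
        n_bins = (self.xi1_bin_max - self.xi1_bin_min) / self.xi1_bin_width
        if n_bins < 2:
            raise ValueError("need at least 2 xi1 bins")
        if self.fes_bins < 2:
            raise ValueError("need at least 2 bins per FES axis")
        if self.b <= 0:
            raise ValueError("bound cutoff b must be positive")
        if self.area_A is not None and self.area_A <= 0:
            raise ValueError("membrane area must be positive")
        if np.isfinite(self.box_Lz) and self.box_Lz <= self.b:
            raise ValueError("box_Lz must exceed the bound cutoff b")

    @property
    def xi1_bin_edges(self) -> np.ndarray:
        n = int(round((self.xi1_bin_max - self.xi1_bin_min) / self.xi1_bin_width))
        return self.xi1_bin_min + self.xi1_bin_width * np.arange(n + 1)

    @property
    def temperature(self) -> float:
        return self.protocol.temperature

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        kwargs = {}
        proto = data.pop("protocol", None)
        if proto is not None:
            p = dict(proto)
            if "centers" in p:
                p["centers"] = tuple(float(c) for c in p["centers"])
            kwargs["protocol"] = UmbrellaProtocol(**p)
        bins = data.pop("xi1_bins", None)
        if bins is not None:
            kwargs["xi1_bin_min"] = float(bins.get("min", 0.35))
            kwargs["xi1_bin_max"] = float(bins.get("max", 1.6))
            kwargs["xi1_bin_width"] = float(bins.get("width", 0.02))
        binding = data.pop("binding", None)
        if binding is not None:
            if "b" in binding:
                kwargs["b"] = float(binding["b"])
            if "area_A" in binding:
                kwargs["area_A"] = float(binding["area_A"])
            if "box_Lz" in binding:
                kwargs["box_Lz"] = float(binding["box_Lz"])
        plateau = data.pop("plateau_region", None)
        if plateau is not None:
            kwargs["plateau_region"] = (float(plateau[0]), float(plateau[1]))
        for key in ("burn_in_fraction", "burn_in_time", "fes_bins",
                    "wham_tolerance", "max_iterations", "n_pip3"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)


def load_config(path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file."""
    return AnalysisConfig.from_file(path)


# ---------------------------------------------------------------------------
# COLVAR dialect
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_ALIASES = {
    "time": "time",
    "d1": "xi1", "xi1": "xi1", "mindist": "xi1",
    "d2": "xi2", "xi2": "xi2", "comdist": "xi2",
    "d3": "xi3", "xi3": "xi3", "costheta": "xi3",
    "window": "window", "replica": "replica",
}


def read_colvar(path, column_map: dict[str, str] | None = None,
                window_index: int = 0) -> CVTrajectory:
    """Read a PLUMED-style COLVAR file into a :class:`CVTrajectory`.

    Column semantics come from the ``#! FIELDS`` header when present
    (field names mapped through ``column_map``, which maps file column
    names to ``time``/``xi1``/``xi2``/``xi3``/``window``/``replica``); a
    file without a header requires an explicit positional ``column_map``
    of the form ``{0: "time", 1: "xi1", ...}``.

    Unparseable data lines raise with their line number; a non-monotonic
    time column is recorded as a warning in the trajectory provenance.
    """
    path = Path(path)
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                toks = s.split()
                if len(toks) >= 2 and toks[1] == "FIELDS":
                    fields = toks[2:]
                continue
            if s.startswith("#") or s.startswith("@"):
                continue
            try:
                rows.append([float(t) for t in s.split()])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable data line: {s!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row at data row {i + 1}")
    data = np.asarray(rows, dtype=float)

    if fields is not None:
        if column_map is None:
            column_map = {}
        mapping = {}
        for j, name in enumerate(fields):
            target = column_map.get(name, _DEFAULT_COLUMN_ALIASES.get(name))
            if target is not None:
                mapping[target] = j
    else:
        if column_map is None:
            raise ValueError(
                f"{path}: no '#! FIELDS' header; an explicit positional "
                "column_map is required")
        mapping = {v: int(k) for k, v in column_map.items()}

    for required in ("time", "xi1"):
        if required not in mapping:
            raise ValueError(f"{path}: required column '{required}' not mapped")
        if mapping[required] >= width:
            raise ValueError(
                f"{path}: column '{required}' mapped to index "
                f"{mapping[required]} but rows have {width} columns")

    def col(name):
        j = mapping.get(name)
        return None if j is None or j >= width else data[:, j]

    time = col("time")
    source = str(path)
    if np.any(np.diff(time) < 0):
        warnings.warn(f"{path}: time column is not monotonic")
        source += " [warning: non-monotonic time]"
    wcol = col("window")
    widx: int | np.ndarray = window_index
    if wcol is not None:
        wvals = wcol.astype(int)
        widx = int(wvals[0]) if np.all(wvals == wvals[0]) else wvals
    rep = col("replica")
    return CVTrajectory(
        time=time, xi1=col("xi1"), xi2=col("xi2"), xi3=col("xi3"),
        window_index=widx,
        replica_index=None if rep is None else rep.astype(int),
        source=source)


def write_colvar(path, traj: CVTrajectory, precision: int = 8) -> None:
    """Write a trajectory in the COLVAR dialect (``#! FIELDS`` header)."""
    names = ["time", "xi1"]
    cols = [traj.time, traj.xi1]
    if traj.xi2 is not None:
        names.append("xi2")
        cols.append(traj.xi2)
    if traj.xi3 is not None:
        names.append("xi3")
        cols.append(traj.xi3)
    wi = traj.window_index
    names.append("window")
    cols.append(np.asarray(wi) if isinstance(wi, np.ndarray)
                else np.full(len(traj), wi))
    if traj.replica_index is not None:
        names.append("replica")
        cols.append(traj.replica_index)
    fmt = f"%.{precision}g"
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(names) + "\n")
        for row in np.column_stack(cols):
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# XVG dialect
# ---------------------------------------------------------------------------

def read_xvg(path, window_index: int = 0) -> CVTrajectory:
    """Read a GROMACS-style .xvg file (``#``/``@`` lines ignored).

    Columns are positional: time, xi1, then optionally xi2 and xi3.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("@"):
                continue
            try:
                vals = [float(t) for t in s.split()]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable data line: {s!r}") from exc
            if rows and len(vals) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(vals)} columns, "
                    f"expected {len(rows[0])})")
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty data section")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least time and one CV column")
    return CVTrajectory(
        time=data[:, 0], xi1=data[:, 1],
        xi2=data[:, 2] if data.shape[1] > 2 else None,
        xi3=data[:, 3] if data.shape[1] > 3 else None,
        window_index=window_index, source=str(path))


def write_xvg(path, traj: CVTrajectory, precision: int = 8) -> None:
    """Write a trajectory in the XVG dialect with ``@`` legend lines."""
    cols = [traj.time, traj.xi1]
    legends = ["xi1 (nm)"]
    if traj.xi2 is not None:
        cols.append(traj.xi2)
        legends.append("xi2 (nm)")
    if traj.xi3 is not None:
        cols.append(traj.xi3)
        legends.append("xi3 (cos theta)")
    fmt = f"%.{precision}g"
    with open(path, "w") as fh:
        fh.write("@    title \"collective variables\"\n")
        fh.write("@    xaxis  label \"time\"\n")
        for i, leg in enumerate(legends):
            fh.write(f"@ s{i} legend \"{leg}\"\n")
        for row in np.column_stack(cols):
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# burn-in
# ---------------------------------------------------------------------------

def apply_burn_in(traj: CVTrajectory, config: AnalysisConfig) -> CVTrajectory:
    """Discard the initial non-equilibrated segment of a trajectory.

    If ``config.burn_in_time`` is set, frames with ``time < burn_in_time``
    are removed; otherwise ``burn_in_fraction`` of the time span from the
    first frame is discarded (the default 2/15 mirrors discarding the
    first 2 us of a 15 us window).
    """
    t = traj.time
    if config.burn_in_time is not None:
        cutoff = config.burn_in_time
    else:
        cutoff = t[0] + config.burn_in_fraction * (t[-1] - t[0])
    if cutoff >= t[-1] and config.burn_in_fraction != 0:
        raise ValueError(
            f"burn-in cutoff {cutoff} is at or beyond the final time {t[-1]}")
    return traj.slice(t >= cutoff)
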