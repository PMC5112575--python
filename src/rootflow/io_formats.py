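"""Readers and writers for the plain-text input dialects and output files.

All dialects are whitespace-delimited with ``#`` comment lines; depths are
metres positive downward (surface = 0, block centres at ``(i - 1/2) dz``),
heads metres, conductivities m/s, water amounts mm.  Field order follows
the documented templates; byte layouts of the historical Fortran files are
deliberately not reproduced.

Input dialects
--------------
soil (ALS-soil)
    ``nz <int>``, ``dz <m>``, optional ``kmean arithmetic|geometric``,
    then one ``layer`` stanza per soil layer, top to bottom::

        layer <bottom_depth_m> vg <theta_r> <theta_s> <alpha_1/m> <n> <Ks_m/s>
        layer <bottom_depth_m> tab <n_ret> <n_cond>
        h <head_m> <theta>      (n_ret lines, h increasing, last at h = 0)
        k <theta> <K_m/s>       (n_cond lines, theta increasing)

init (INITF)
    one water content per line, nz lines, surface block first.
term (TERMF)
    measured water contents: ``<depth_m> <theta>`` rows (taken to be the
    final simulation day) or ``<day> <depth_m> <theta>`` rows.
weather (WEA2)
    one day per row, columns in order:
    ``day  et0_mm/day  tair_C  rain_mm/day  rh_fraction  lai``.

Outputs: OUTS (daily heads), OUTS2 (daily head/theta per depth), INFS
(daily surface-flux and infiltration summary), WUE (daily cumulative water
losses) from a single run; ARD, C_AEVA, C_ATRA, WBELOW, WADD, BIGI and
PCTDIF matrices indexed by (beta, Zr) from a search.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .hydraulics import SoilProfile, TabulatedCurve, VanGenuchten
from .solver import Grid
from .surface import WeatherRecord

__all__ = [
    "ParseError",
    "InputBundle",
    "read_soil",
    "read_init",
    "read_term",
    "read_weather",
    "read_bundle",
    "write_soil",
    "write_init",
    "write_term",
    "write_weather",
    "interpolate_profile",
    "write_run_outputs",
    "write_search_outputs",
    "RUN_OUTPUT_FILES",
    "SEARCH_OUTPUT_FILES",
]

RUN_OUTPUT_FILES = ("OUTS.DAT", "OUTS2.DAT", "INFS.DAT", "WUE.DAT")
SEARCH_OUTPUT_FILES = (
    "ARD.DAT",
    "C_AEVA.DAT",
    "C_ATRA.DAT",
    "WBELOW.DAT",
    "WADD.DAT",
    "BIGI.DAT",
    "PCTDIF.DAT",
)


class ParseError(ValueError):
    """A malformed input file; message carries file, line and expectation."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class InputBundle:
    """Everything a forward run or a search needs, parsed and validated."""

    grid: Grid
    profile: SoilProfile
    initial_theta: np.ndarray
    weather: list
    observations: list | None = None  # (day|None, depth, theta) triples
    kmean: str = "arithmetic"


def _data_lines(path):
    """Yield (lineno, tokens) for non-comment, non-blank lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                yield lineno, line.split()


def _num(tok, path, lineno, what):
    try:
        return float(tok)
    except ValueError:
        raise ParseError(path, lineno, f"expected numeric {what}, got '{tok}'") from None


def read_soil(path) -> tuple[Grid, SoilProfile, str]:
    """Parse an ALS-soil dialect file into (grid, profile, kmean)."""
    nz = dz = None
    kmean = "arithmetic"
    layers = []
    lines = list(_data_lines(path))
    i = 0
    while i < len(lines):
        lineno, toks = lines[i]
        key = toks[0].lower()
        if key == "nz":
            nz = int(_num(toks[1], path, lineno, "nz"))
        elif key == "dz":
            dz = _num(toks[1], path, lineno, "dz")
        elif key == "kmean":
            if toks[1] not in ("arithmetic", "geometric"):
                raise ParseError(path, lineno, f"unknown kmean '{toks[1]}'")
            kmean = toks[1]
        elif key == "layer":
            bottom = _num(toks[1], path, lineno, "layer bottom depth")
            form = toks[2].lower()
            name = f"layer{len(layers) + 1}"
            if form == "vg":
                if len(toks) != 8:
                    raise ParseError(
                        path, lineno,
                        "vg layer needs: bottom vg theta_r theta_s alpha n Ks",
                    )
                vals = [_num(t, path, lineno, "vg parameter") for t in toks[3:8]]
                try:
                    mat = VanGenuchten(*vals, name=name)
                except ValueError as err:
                    raise ParseError(path, lineno, str(err)) from None
            elif form == "tab":
                n_ret = int(_num(toks[3], path, lineno, "n_ret"))
                n_cond = int(_num(toks[4], path, lineno, "n_cond"))
                hs, ths, tks, ks = [], [], [], []
                for k in range(n_ret):
                    i += 1
                    ln2, t2 = lines[i]
                    if t2[0].lower() != "h" or len(t2) != 3:
                        raise ParseError(path, ln2, "expected 'h <head> <theta>'")
                    hs.append(_num(t2[1], path, ln2, "head"))
                    ths.append(_num(t2[2], path, ln2, "theta"))
                for k in range(n_cond):
                    i += 1
                    ln2, t2 = lines[i]
                    if t2[0].lower() != "k" or len(t2) != 3:
                        raise ParseError(path, ln2, "expected 'k <theta> <K>'")
                    tks.append(_num(t2[1], path, ln2, "theta"))
                    ks.append(_num(t2[2], path, ln2, "conductivity"))
                try:
                    mat = TabulatedCurve(tuple(hs), tuple(ths), tuple(tks), tuple(ks), name=name)
                except ValueError as err:
                    raise ParseError(path, lineno, str(err)) from None
            else:
                raise ParseError(path, lineno, f"unknown layer form '{form}'")
            layers.append((bottom, mat))
        else:
            raise ParseError(path, lineno, f"unknown key '{toks[0]}'")
        i += 1
    if nz is None or dz is None or not layers:
        raise ParseError(path, 0, "soil file needs nz, dz and at least one layer")
    grid = Grid(nz=nz, dz=dz)
    profile = SoilProfile(tuple(layers))
    if abs(grid.z_max - profile.z_max) > 1e-9 and grid.z_max > profile.z_max:
        raise ParseError(path, 0, f"grid depth {grid.z_max} exceeds last layer {profile.z_max}")
    return grid, profile, kmean


def read_init(path, grid: Grid, profile: SoilProfile | None = None) -> np.ndarray:
    """Parse an INITF dialect file: nz water contents, surface first."""
    vals = []
    for lineno, toks in _data_lines(path):
        for tok in toks:
            vals.append(_num(tok, path, lineno, "water content"))
    if len(vals) != grid.nz:
        raise ParseError(path, 0, f"expected {grid.nz} water contents, got {len(vals)}")
    theta = np.asarray(vals)
    if profile is not None:
        props = profile.bind(grid)
        bad = np.flatnonzero(
            (theta < props.theta_r - 1e-9) | (theta > props.theta_s + 1e-9)
        )
        if bad.size:
            raise ParseError(
                path, 0,
                f"water content out of layer range at block(s) {bad.tolist()}",
            )
    return theta


def read_term(path) -> list:
    """Parse a TERMF dialect file into (day_or_None, depth, theta) triples."""
    obs = []
    for lineno, toks in _data_lines(path):
        if len(toks) == 2:
            depth = _num(toks[0], path, lineno, "depth")
            th = _num(toks[1], path, lineno, "theta")
            obs.append((None, depth, th))
        elif len(toks) == 3:
            day = int(_num(toks[0], path, lineno, "day"))
            depth = _num(toks[1], path, lineno, "depth")
            th = _num(toks[2], path, lineno, "theta")
            obs.append((day, depth, th))
        else:
            raise ParseError(
                path, lineno, f"expected 2 or 3 columns, got {len(toks)}"
            )
        if th <= 0:
            raise ParseError(path, lineno, f"non-positive water content {th}")
    if not obs:
        raise ParseError(path, 0, "no observations found")
    return obs


def read_weather(path) -> list:
    """Parse a WEA2 dialect file into WeatherRecords; days must be contiguous."""
    recs = []
    for lineno, toks in _data_lines(path):
        if len(toks) != 6:
            raise ParseError(
                path, lineno,
                f"expected 6 columns (day et0 tair rain rh lai), got {len(toks)}",
            )
        day = int(_num(toks[0], path, lineno, "day"))
        vals = [_num(t, path, lineno, name)
                for t, name in zip(toks[1:], ("et0", "tair", "rain", "rh", "lai"))]
        try:
            recs.append(WeatherRecord(day, *vals))
        except ValueError as err:
            raise ParseError(path, lineno, str(err)) from None
        if len(recs) > 1 and recs[-1].day != recs[-2].day + 1:
            raise ParseError(
                path, lineno,
                f"non-contiguous days: {recs[-2].day} then {recs[-1].day}",
            )
    if not recs:
        raise ParseError(path, 0, "no weather rows found")
    return recs


def read_bundle(soil_path, init_path, weather_path, term_path=None) -> InputBundle:
    grid, profile, kmean = read_soil(soil_path)
    theta0 = read_init(init_path, grid, profile)
    weather = read_weather(weather_path)
    obs = read_term(term_path) if term_path is not None else None
    return InputBundle(grid, profile, theta0, weather, obs, kmean)


def interpolate_profile(pairs, grid: Grid) -> np.ndarray:
    """Linear interpolation of sparse (depth, theta) pairs to block centres.

    Flat extrapolation beyond the outermost measurements.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 (depth, theta) pairs")
    depths = np.array([p[0] for p in pairs], float)
    thetas = np.array([p[1] for p in pairs], float)
    order = np.argsort(depths)
    depths, thetas = depths[order], thetas[order]
    if np.any(np.diff(depths) == 0):
        raise ValueError("duplicate measurement depths")
    if depths[0] < 0 or depths[-1] > grid.z_max + 1e-9:
        raise ValueError("measurement depths outside [0, z_max]")
    return np.interp(grid.z_centers, depths, thetas)


# ---------------------------------------------------------------------------
# writers

_HDR = "# rootflow {name} — {desc}\n# depths m positive downward; heads m; water amounts mm\n"


def write_soil(path, grid: Grid, profile: SoilProfile, kmean: str = "arithmetic"):
    with open(path, "w") as fh:
        fh.write(_HDR.format(name="soil (ALS-soil dialect)", desc="grid and layer hydraulics"))
        fh.write(f"nz {grid.nz}\ndz {grid.dz:.6g}\nkmean {kmean}\n")
        for bottom, mat in profile.layers:
            if isinstance(mat, VanGenuchten):
                fh.write(
                    f"layer {bottom:.6g} vg {mat.theta_r:.6g} {mat.theta_s:.6g} "
                    f"{mat.alpha:.6g} {mat.n:.6g} {mat.K_s:.6g}\n"
                )
            else:
                fh.write(
                    f"layer {bottom:.6g} tab {len(mat.h_nodes)} {len(mat.thetak_nodes)}\n"
                )
                for h, th in zip(mat.h_nodes, mat.theta_nodes):
                    fh.write(f"h {h:.6g} {th:.6g}\n")
                for th, k in zip(mat.thetak_nodes, mat.k_nodes):
                    fh.write(f"k {th:.6g} {k:.6g}\n")


def write_init(path, theta: np.ndarray):
    with open(path, "w") as fh:
        fh.write(_HDR.format(name="init (INITF dialect)", desc="one theta per block, surface first"))
        for th in theta:
            fh.write(f"{th:.6f}\n")


def write_term(path, observations):
    """observations: iterable of (day_or_None, depth, theta)."""
    with open(path, "w") as fh:
        fh.write(_HDR.format(name="term (TERMF dialect)", desc="measured water contents"))
        for day, depth, th in observations:
            if day is None:
                fh.write(f"{depth:.4f} {th:.6f}\n")
            else:
                fh.write(f"{int(day)} {depth:.4f} {th:.6f}\n")


def write_weather(path, records):
    with open(path, "w") as fh:
        fh.write(_HDR.format(name="weather (WEA2 dialect)", desc="day et0 tair rain rh lai"))
        for r in records:
            fh.write(
                f"{r.day} {r.et0:.4f} {r.tair:.2f} {r.rain:.4f} {r.rh:.4f} {r.lai:.4f}\n"
            )


def write_run_outputs(run, outdir):
    """Write OUTS, OUTS2, INFS and WUE for one forward run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    zc = run.grid.z_centers

    with open(outdir / "OUTS.DAT", "w") as fh:
        fh.write(_HDR.format(name="OUTS", desc="daily pressure heads per block centre"))
        fh.write("# day  " + "  ".join(f"h@{z:.3f}" for z in zc) + "\n")
        for i, day in enumerate(run.days):
            fh.write(f"{day} " + " ".join(f"{v:.6e}" for v in run.head[i]) + "\n")

    with open(outdir / "OUTS2.DAT", "w") as fh:
        fh.write(_HDR.format(name="OUTS2", desc="daily head and water content per depth"))
        fh.write("# day depth head theta\n")
        for i, day in enumerate(run.days):
            for j, z in enumerate(zc):
                fh.write(f"{day} {z:.4f} {run.head[i, j]:.6e} {run.theta[i, j]:.6f}\n")

    led = run.ledger
    with open(outdir / "INFS.DAT", "w") as fh:
        fh.write(_HDR.format(name="INFS", desc="daily infiltration and drainage summary"))
        fh.write("# day rain wadd bigi wbelow storage\n")
        for _, r in led.iterrows():
            fh.write(
                f"{int(r['day'])} {r['rain']:.4f} {r['wadd']:.4f} "
                f"{r['bigi']:.4f} {r['wbelow']:.4f} {r['storage']:.4f}\n"
            )

    with open(outdir / "WUE.DAT", "w") as fh:
        fh.write(_HDR.format(name="WUE", desc="daily cumulative water losses"))
        fh.write("# day c_aeva c_atra bigi wbelow wadd pctdif\n")
        for _, r in led.iterrows():
            fh.write(
                f"{int(r['day'])} {r['c_aeva']:.4f} {r['c_atra']:.4f} "
                f"{r['bigi']:.4f} {r['wbelow']:.4f} {r['wadd']:.4f} {r['pctdif']:.4f}\n"
            )


def _write_grid_file(path, name, desc, betas, zrmaxs, matrix):
    with open(path, "w") as fh:
        fh.write(_HDR.format(name=name, desc=desc))
        fh.write("# rows: beta (first column); columns: zr_max (header row)\n")
        fh.write("beta\\zr " + " ".join(f"{z:.4f}" for z in zrmaxs) + "\n")
        for b, row in zip(betas, matrix):
            fh.write(f"{b:.4f} " + " ".join(f"{v:.6e}" for v in row) + "\n")


def write_search_outputs(result, outdir):
    """Write the seven (beta, Zr) grid files of a search."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    descs = {
        "ARD.DAT": ("ARD", "average relative discrepancy sim vs measured theta (-)"),
        "C_AEVA.DAT": ("C_AEVA", "cumulative soil evaporation (mm)"),
        "C_ATRA.DAT": ("C_ATRA", "cumulative transpiration (mm)"),
        "WBELOW.DAT": ("WBELOW", "drainage below the root zone (mm)"),
        "WADD.DAT": ("WADD", "water added at the surface (mm)"),
        "BIGI.DAT": ("BIGI", "cumulative infiltration (mm)"),
        "PCTDIF.DAT": ("PCTDIF", "percent water-balance difference (%)"),
    }
    mats = {
        "ARD.DAT": result.ard,
        "C_AEVA.DAT": result.c_aeva,
        "C_ATRA.DAT": result.c_atra,
        "WBELOW.DAT": result.wbelow,
        "WADD.DAT": result.wadd,
        "BIGI.DAT": result.bigi,
        "PCTDIF.DAT": result.pctdif,
    }
    for fname in SEARCH_OUTPUT_FILES:
        name, desc = descs[fname]
        _write_grid_file(outdir / fname, name, desc, result.betas, result.zrmaxs, mats[fname])
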