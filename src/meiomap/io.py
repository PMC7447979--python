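"""Readers and writers for the package's tabular formats.

File intervals are 0-based, half-open (BED convention).  Coverage goes to
4-column bedGraph, one file per strand; hotspot catalogs, outcome records,
focus/axis coordinates and per-position maps are tab-separated tables with
a header line; generator configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binstats import BIN_WIDTH
from .deconvolution import DeconvolvedProfile, OffsetDistribution
from .profiles import StrandProfile
from .synthetic import GeneratorConfig, OffsetModel

HOTSPOT_HALF_WIDTH = 250  # bp written around the motif midpoint in BED output


# -- hotspot catalogs --------------------------------------------------------

def write_hotspots(hotspots: pd.DataFrame, path) -> None:
    df = hotspots.copy()
    df.insert(1, "start", df["center"] - HOTSPOT_HALF_WIDTH - 1)
    df.insert(2, "end", df["center"] + HOTSPOT_HALF_WIDTH)
    df.to_csv(path, sep="\t", index=False)


def read_hotspots(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.drop(columns=[c for c in ("start", "end") if c in df])


# -- coverage ----------------------------------------------------------------

def write_coverage_bedgraph(profiles, crick_path, watson_path) -> None:
    """One bedGraph per strand; zero-coverage bins are omitted."""
    for path, strand in ((crick_path, "crick"), (watson_path, "watson")):
        rows = []
        for p in profiles:
            values = getattr(p, strand)
            centers = p.bin_centers() + int(p.origin)
            nz = values != 0
            half = p.bin_width // 2
            rows.append(pd.DataFrame({
                "chrom": p.chrom,
                "start": centers[nz] - half - 1,
                "end": centers[nz] + half - 1,
                "value": values[nz],
            }))
        out = (pd.concat(rows, ignore_index=True) if rows
               else pd.DataFrame(columns=["chrom", "start", "end", "value"]))
        out.to_csv(path, sep="\t", index=False, header=False)


def read_coverage_bedgraph(crick_path, watson_path, hotspots: pd.DataFrame,
                           span: int = 6000, bin_width: int = BIN_WIDTH):
    """Rebuild per-hotspot StrandProfiles from strand bedGraphs."""
    m = span // bin_width
    centers = hotspots["center"].to_numpy()
    chroms = hotspots["chrom"].to_numpy()
    arrays = {s: np.zeros((len(centers), 2 * m + 1))
              for s in ("crick", "watson")}
    order = np.argsort(centers)
    sorted_centers = centers[order]
    for path, strand in ((crick_path, "crick"), (watson_path, "watson")):
        bg = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        mid = (bg["start"] + 1 + bg["end"] + 1) // 2  # interval midpoint, 1-based
        pos = np.searchsorted(sorted_centers, mid)
        pos = np.clip(pos, 1, len(sorted_centers) - 1) if len(centers) > 1 else np.zeros(len(mid), int)
        left = sorted_centers[np.maximum(pos - 1, 0)]
        right = sorted_centers[np.minimum(pos, len(sorted_centers) - 1)]
        nearest = np.where(np.abs(mid - left) <= np.abs(right - mid),
                           np.maximum(pos - 1, 0), np.minimum(pos, len(sorted_centers) - 1))
        hot_idx = order[nearest]
        rel = mid.to_numpy() - centers[hot_idx]
        bins = np.floor(rel / bin_width + 0.5).astype(int)
        ok = np.abs(bins) <= m
        arrays[strand][hot_idx[ok], bins[ok] + m] += bg["value"].to_numpy()[ok]
    return [StrandProfile(arrays["crick"][i], arrays["watson"][i], bin_width,
                          origin=centers[i], chrom=chroms[i])
            for i in range(len(centers))]


# -- aggregate tracks and solver inputs/outputs ------------------------------

def write_track(bp, values, path, value_name: str = "value") -> None:
    pd.DataFrame({"bp": np.asarray(bp), value_name: np.asarray(values)}).to_csv(
        path, sep="\t", index=False)


def read_track(path):
    df = pd.read_csv(path, sep="\t")
    return df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()


def write_offsets(s: OffsetDistribution, path) -> None:
    m = s.m
    pd.DataFrame({
        "bin": np.arange(-m, m + 1),
        "bp": np.arange(-m, m + 1) * s.bin_width,
        "count": s.counts,
    }).to_csv(path, sep="\t", index=False)


def read_offsets(path) -> OffsetDistribution:
    df = pd.read_csv(path, sep="\t")
    return OffsetDistribution(df["count"].to_numpy(dtype=float))


def write_deconvolved(dp: DeconvolvedProfile, path) -> None:
    k = np.arange(len(dp.b_crick)) + dp.k_lo
    pd.DataFrame({
        "k": k,
        "bp": k * dp.bin_width,
        "b_crick": dp.b_crick,
        "b_watson": dp.b_watson,
        "b_mean": dp.b_mean,
    }).to_csv(path, sep="\t", index=False)


def read_deconvolved(path) -> DeconvolvedProfile:
    df = pd.read_csv(path, sep="\t")
    return DeconvolvedProfile(df["b_crick"].to_numpy(), df["b_watson"].to_numpy(),
                              k_lo=int(df["k"].iloc[0]))


# -- recombination outcomes --------------------------------------------------

def write_crossovers(co: pd.DataFrame, path) -> None:
    df = co.copy()
    df["internal_snps"] = df["internal_snps"].apply(
        lambda xs: ",".join(f"{x:.1f}" for x in xs))
    df.to_csv(path, sep="\t", index=False)


def read_crossovers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["internal_snps"] = df["internal_snps"].fillna("").apply(
        lambda s: [float(x) for x in str(s).split(",") if x not in ("", "nan")])
    return df


def write_ncos(nco: pd.DataFrame, path) -> None:
    nco.to_csv(path, sep="\t", index=False)


def read_ncos(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- foci --------------------------------------------------------------------

def write_foci(foci: pd.DataFrame, path) -> None:
    foci.to_csv(path, sep="\t", index=False)


def read_foci(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


write_axes = write_foci
read_axes = read_foci


# -- configuration -----------------------------------------------------------

def config_to_yaml(config: GeneratorConfig, path) -> None:
    """Serialize a generator config; kernels are stored by name only
    (custom kernels must be reattached programmatically)."""
    d = dataclasses.asdict(config)
    for key in ("kernel_dmc1", "kernel_rad51", "kernel_rpa_template"):
        k = getattr(config, key)
        d[key] = None if k is None else (k.name or "custom")
    d["dsb_offset_model"] = dataclasses.asdict(config.dsb_offset_model)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_builtin(d), fh, sort_keys=True)


def config_from_yaml(path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    om = d.pop("dsb_offset_model", None)
    for key in ("kernel_dmc1", "kernel_rad51", "kernel_rpa_template"):
        if isinstance(d.get(key), str):
            d[key] = None  # defaults are resolved lazily by name
    cfg = GeneratorConfig(**{k: _retuple(v) for k, v in d.items()})
    if om:
        om["flanks"] = tuple(tuple(f) for f in om.get("flanks", ()))
        om["bounds"] = tuple(om.get("bounds", (-1000.0, 1000.0)))
        cfg = dataclasses.replace(cfg, dsb_offset_model=OffsetModel(**om))
    return cfg


def _retuple(v):
    return tuple(v) if isinstance(v, list) else v


def _to_builtin(obj):
    if isinstance(obj, dict):
        return {k: _to_builtin(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_builtin(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_builtin(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
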