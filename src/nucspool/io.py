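"""Trace-schema readers/writers, run configuration, and summary reports.

Interchange format: plain TSV with a versioned header comment and columns
``time_s  force_pN  extension_nm  direction  cycle`` plus optional
``donor_counts  acceptor_counts``.  Fluorescence bins (10 ms) are wider than
force samples (1 ms); donor/acceptor values are stored on the force rows
nearest each fluorescence bin centre and blank elsewhere, so a file round-
trips losslessly when the fluorescence rate divides the sampling rate.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .data import FluorescenceTrace, ForceExtensionTrace
from .disassembly import DisassemblyModel
from .simulate import CycleResult, GeneratorConfig
from .spool import SpoolGeometry
from .wlc import WLCParams

__all__ = [
    "SCHEMA_VERSION",
    "PairedTrace",
    "RunConfig",
    "load_config",
    "read_traces",
    "write_traces",
    "run_report",
]

SCHEMA_VERSION = "nucspool-trace-v1"
_REQUIRED = ["time_s", "force_pN", "extension_nm", "direction", "cycle"]
_FLUOR = ["donor_counts", "acceptor_counts"]


@dataclass
class PairedTrace:
    fe: ForceExtensionTrace
    fluor: FluorescenceTrace | None = None


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable run configuration (JSON block per module)."""

    seed: int = 0
    out_dir: str = "results"
    wlc: WLCParams = WLCParams()
    geometry: SpoolGeometry = SpoolGeometry()
    detection: dict = field(default_factory=lambda: {
        "min_step_nm": 5.0, "window": 25})
    alignment: dict = field(default_factory=lambda: {"count_floor": 10.0})
    disassembly: DisassemblyModel = field(default_factory=DisassemblyModel)
    generator: GeneratorConfig = GeneratorConfig()

    def generator_config(self) -> GeneratorConfig:
        """Generator config with wlc/geometry/seed blocks propagated."""
        return replace(self.generator, wlc=self.wlc, geometry=self.geometry,
                       seed=self.seed)


_WLC_KEYS = {"lp_nm": "persistence_length", "s_pn": "stretch_modulus",
             "kt_pn_nm": "thermal_energy", "rise_nm": "rise_per_bp"}
_GEOM_KEYS = {"radius_nm": "superhelix_radius", "pitch_nm": "superhelix_pitch",
              "wrap_bp": "total_wrap_bp", "turns": "total_turns",
              "sphere_radius_nm": "effective_sphere_radius",
              "low_force_release_bp": "low_force_release_bp",
              "post_rip_wrapped_bp": "post_rip_wrapped_bp"}


def _mapped(block: dict, mapping: dict, name: str) -> dict:
    unknown = set(block) - set(mapping)
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    return {mapping[k]: v for k, v in block.items()}


def load_config(path) -> RunConfig:
    """Read a JSON run configuration; unknown keys raise an explicit error."""
    with open(path) as fh:
        raw = json.load(fh)
    known = {"seed", "out", "wlc", "geometry", "detection", "alignment",
             "disassembly", "generator"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "out" in raw:
        kwargs["out_dir"] = str(raw["out"])
    if "wlc" in raw:
        kwargs["wlc"] = WLCParams(**_mapped(raw["wlc"], _WLC_KEYS, "wlc"))
    if "geometry" in raw:
        kwargs["geometry"] = SpoolGeometry(
            **_mapped(raw["geometry"], _GEOM_KEYS, "geometry"))
    for blk in ("detection", "alignment"):
        if blk in raw:
            defaults = RunConfig().__getattribute__(blk)
            unknown = set(raw[blk]) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in config block {blk!r}: "
                                 f"{sorted(unknown)}")
            kwargs[blk] = {**defaults, **raw[blk]}
    if "disassembly" in raw:
        kwargs["disassembly"] = DisassemblyModel(outcomes=raw["disassembly"])
    if "generator" in raw:
        valid = set(GeneratorConfig.__dataclass_fields__)
        unknown = set(raw["generator"]) - valid
        if unknown:
            raise ValueError(f"unknown keys in config block 'generator': "
                             f"{sorted(unknown)}")
        gen_kwargs = {k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in raw["generator"].items()}
        kwargs["generator"] = GeneratorConfig(**gen_kwargs)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# trace TSV round trip
# ---------------------------------------------------------------------------

def write_traces(traces: list[PairedTrace | ForceExtensionTrace], path) -> None:
    """Write paired traces to one TSV file in the interchange schema."""
    frames = []
    for item in traces:
        pt = item if isinstance(item, PairedTrace) else PairedTrace(item)
        fe = pt.fe
        df = pd.DataFrame({
            "time_s": fe.time, "force_pN": fe.force,
            "extension_nm": fe.extension,
            "direction": fe.direction, "cycle": fe.cycle_index,
        })
        if pt.fluor is not None:
            df["donor_counts"] = np.nan
            df["acceptor_counts"] = np.nan
            idx = np.searchsorted(fe.time, pt.fluor.time)
            idx = np.clip(idx, 0, len(fe.time) - 1)
            df.loc[idx, "donor_counts"] = pt.fluor.donor_counts
            df.loc[idx, "acceptor_counts"] = pt.fluor.acceptor_counts
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_traces(path) -> list[PairedTrace]:
    """Read an interchange TSV back into paired traces.

    Raises a schema error naming missing columns or the first row where
    time is non-monotone within a trace group.
    """
    with open(path) as fh:
        first = fh.readline()
        body = fh.read()
    header_rows = 0 if first.startswith("#") else None
    text = body if header_rows == 0 else first + body
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: missing columns {missing}")
    has_fluor = all(c in df.columns for c in _FLUOR)
    out = []
    for (cycle, direction), grp in df.groupby(["cycle", "direction"], sort=True):
        grp = grp.reset_index(drop=True)
        t = grp["time_s"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if len(bad):
            raise ValueError(f"schema error: non-monotone time at row "
                             f"{int(bad[0]) + 1} of cycle {cycle} {direction}")
        fe = ForceExtensionTrace(t, grp["force_pN"].to_numpy(),
                                 grp["extension_nm"].to_numpy(),
                                 direction=str(direction),
                                 cycle_index=int(cycle))
        fluor = None
        if has_fluor:
            mask = grp["donor_counts"].notna() & grp["acceptor_counts"].notna()
            if mask.sum() >= 2:
                fluor = FluorescenceTrace(
                    t[mask.to_numpy()],
                    grp.loc[mask, "donor_counts"].to_numpy(),
                    grp.loc[mask, "acceptor_counts"].to_numpy())
        out.append(PairedTrace(fe, fluor))
    return out


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

def run_report(molecules: list[list[CycleResult]], config: RunConfig,
               reference_dna: ForceExtensionTrace | None = None) -> dict:
    """Summary tables over an analysed archive of simulated molecules.

    Runs detection/classification on every pulling trace and returns
    deterministic DataFrames: per-species transition force / delta-x
    means +- SD, offsets vs bare DNA, and first-cycle outcome fractions.
    """
    from .traces import classify_species, measure_offset_vs_reference

    if not molecules:
        raise ValueError("empty archive")
    rows, offsets, outcomes = [], [], []
    for m, cycles in enumerate(molecules):
        for res in cycles:
            call = classify_species(res.pull, params=config.wlc)
            for ev in call.evidence:
                rows.append(dict(molecule=m, cycle=res.pull.cycle_index,
                                 species=call.label, kind=ev.kind,
                                 force_pN=ev.force, delta_x_nm=ev.delta_x,
                                 hopping=ev.hopping))
            if reference_dna is not None and call.label != "bareDNA":
                try:
                    off = measure_offset_vs_reference(reference_dna, res.pull,
                                                      params=config.wlc)
                    offsets.append(dict(molecule=m, species=call.label,
                                        offset_nm=off))
                except ValueError:
                    pass
            if res.pull.cycle_index == 0:
                outcomes.append(res.truth.species if not cycles[1:] else
                                cycles[1].truth.species)
    events = pd.DataFrame(rows)
    summary = (events.groupby(["species", "kind"])
               .agg(n=("delta_x_nm", "size"),
                    force_mean=("force_pN", "mean"),
                    force_sd=("force_pN", "std"),
                    dx_mean=("delta_x_nm", "mean"),
                    dx_sd=("delta_x_nm", "std"))
               .reset_index()) if len(events) else pd.DataFrame()
    offset_df = pd.DataFrame(offsets)
    offset_summary = (offset_df.groupby("species")["offset_nm"]
                      .agg(["mean", "std", "size"]).reset_index()
                      ) if len(offset_df) else pd.DataFrame()
    frac = pd.Series(outcomes).value_counts(normalize=True).to_dict() \
        if outcomes else {}
    return {"events": events, "summary": summary,
            "offsets": offset_summary, "first_cycle_fractions": frac}


def export_report(report: dict, out_dir) -> None:
    import pathlib
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("events", "summary", "offsets"):
        df = report[name]
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.4f")
    with open(out / "first_cycle_fractions.json", "w") as fh:
        json.dump(report["first_cycle_fractions"], fh, indent=1, sort_keys=True)
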