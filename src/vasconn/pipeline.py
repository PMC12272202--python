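"""End-to-end orchestration: phantom/real inputs -> masks -> preprocessing ->
connectivity -> perivascular profiles (-> RSN occupancy), with provenance.

A :class:`RunConfig` captures every stage parameter and round-trips through
YAML; :func:`run_pipeline` executes the stages in order, writes NIfTI metric
maps and TSV tables, and records a JSON manifest.  Reruns with an identical
config and seed produce byte-identical TSV outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    ConnectivityMaps,
    category_metrics,
    group_summarize,
    ratio_maps,
)
from .grid import BinaryMask, Bold4D, VesselLabelMap
from .masks import make_shells, restrict_to_gm, split_by_label
from .occupancy import occupancy_table
from .perivascular import shell_metrics
from .phantom import PhantomSpec, make_phantom
from .preprocess import preprocess_bold

__all__ = ["ConfigError", "StageError", "RunConfig", "run_pipeline"]

_FLOAT_FMT = "%.12g"  # stable TSV float formatting (determinism contract)


class ConfigError(ValueError):
    """Invalid run configuration (nothing has been executed)."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_REQUIRED_DATA_KEYS = ("bold", "labels", "gm", "wm", "csf")


@dataclass
class RunConfig:
    """Serializable parameters for one pipeline run."""

    phantom: dict | None = None  # PhantomSpec keyword overrides
    data: dict | None = None  # paths: bold, labels, gm, wm, csf [, brain, tr_s]
    threshold: float = 0.15
    mode: str = "absolute"
    band: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float | None = 6.0
    K: int = 3
    connectivity: int = 26
    block_size: int = 256
    rng_seed: int = 0
    occupancy: dict | None = None  # paths: rsn (dir or mapping), freq [, z, pct]

    def validate(self) -> None:
        if (self.phantom is None) == (self.data is None):
            raise ConfigError("exactly one of 'phantom' or 'data' must be given")
        if self.data is not None:
            missing = [k for k in _REQUIRED_DATA_KEYS if k not in self.data]
            if missing:
                raise ConfigError(f"data config missing required paths: {missing}")
            for k in _REQUIRED_DATA_KEYS:
                if not Path(self.data[k]).exists():
                    raise ConfigError(f"data path for {k!r} does not exist: {self.data[k]}")
        if self.phantom is not None:
            try:
                self._phantom_spec()
            except Exception as e:
                raise ConfigError(f"invalid phantom spec: {e}") from e
        if not (0.0 < self.threshold < 1.0):
            raise ConfigError(f"threshold must lie in (0,1): {self.threshold}")
        if self.mode not in ("absolute", "positive"):
            raise ConfigError(f"mode must be absolute|positive: {self.mode!r}")
        if not (0.0 <= self.band[0] < self.band[1]):
            raise ConfigError(f"invalid band {self.band}")
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        if self.occupancy is not None and "freq" not in self.occupancy:
            raise ConfigError("occupancy config requires a 'freq' map path")

    def _phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom or {})
        kw.setdefault("rng_seed", self.rng_seed)
        if "grid_dims" in kw:
            kw["grid_dims"] = tuple(kw["grid_dims"])
        if "voxel_size_mm" in kw:
            kw["voxel_size_mm"] = tuple(kw["voxel_size_mm"])
        return PhantomSpec(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band" in d and d["band"] is not None:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


_HIST_EDGES = {
    "D_norm": np.linspace(0.0, 1.0, 41),
    "S_pos": np.linspace(0.0, 1.0, 41),
    "S_neg": np.linspace(-1.0, 0.0, 41),
    "S_all": np.linspace(-1.0, 1.0, 41),
    "var_pos": np.linspace(0.0, 1.0, 41),
    "var_neg": np.linspace(0.0, 1.0, 41),
    "var_all": np.linspace(0.0, 1.0, 41),
    "D_ratio": np.linspace(0.0, 5.0, 51),
    "var_ratio_pos": np.linspace(0.0, 5.0, 51),
    "var_ratio_neg": np.linspace(0.0, 5.0, 51),
    "var_ratio_all": np.linspace(0.0, 5.0, 51),
}


def _histogram_rows(category: str, m) -> list[dict]:
    rows = []
    if isinstance(m, ConnectivityMaps):
        metric_values = {
            "D_norm": m.D / np.maximum(m.n_targets_valid, 1),
            **{k: m.metric(k) for k in ("S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all")},
        }
    else:
        metric_values = {k: m.metric(k) for k in ("D_ratio", "var_ratio_pos", "var_ratio_neg", "var_ratio_all")}
    for metric, vals in metric_values.items():
        vals = vals[~np.isnan(vals)]
        edges = _HIST_EDGES[metric]
        counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1]), bins=edges)
        for b, c in enumerate(counts):
            if c:
                rows.append(
                    {
                        "category": category,
                        "metric": metric,
                        "bin_lo": edges[b],
                        "bin_hi": edges[b + 1],
                        "count": int(c),
                    }
                )
    return rows


def _save_maps(maps: dict, out: Path, prefix: str, manifest_files: list[str]) -> None:
    import nibabel as nib

    for cat, m in maps.items():
        metrics = (
            ("D", "S_pos", "S_neg", "S_all", "var_pos", "var_neg", "var_all")
            if isinstance(m, ConnectivityMaps)
            else ("D_ratio", "var_ratio_pos", "var_ratio_neg", "var_ratio_all")
        )
        safe_cat = cat.replace(":", "_to_").replace("(", "_").replace(")", "").replace(">", "").replace("=", "")
        for metric in metrics:
            name = f"{prefix}{safe_cat}_{metric}.nii"
            nib.save(
                nib.Nifti1Image(m.to_volume(metric).astype(np.float32), m.grid.affine),
                str(out / name),
            )
            manifest_files.append(name)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Fails fast on configuration errors (no stage runs); a stage failure
    retains earlier outputs and marks the failure point in the manifest.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "software": {"name": "vasconn", "version": __version__, "numpy": np.__version__},
        "config": config.to_dict(),
        "rng_seed": config.rng_seed,
        "stages": [],
        "files": [],
        "status": "running",
    }
    stage = "inputs"
    try:
        # ---- stage: inputs -------------------------------------------------
        if config.phantom is not None:
            spec = config._phantom_spec()
            ph = make_phantom(spec)
            bold, labels = ph.bold, ph.labels
            gm, wm, csf, brain = ph.gm, ph.wm, ph.csf, ph.brain
            manifest["inputs"] = {"phantom_spec": spec.to_dict()}
        else:
            d = config.data
            bold = Bold4D.load(d["bold"], tr_s=d.get("tr_s"))
            labels = VesselLabelMap.load(d["labels"])
            gm = BinaryMask.load(d["gm"])
            wm = BinaryMask.load(d["wm"])
            csf = BinaryMask.load(d["csf"])
            brain = (
                BinaryMask.load(d["brain"])
                if "brain" in d
                else BinaryMask(gm.grid, gm.data | wm.data | csf.data)
            )
            manifest["inputs"] = {
                k: {"path": str(d[k]), "sha256": _sha256(Path(d[k]))}
                for k in _REQUIRED_DATA_KEYS
            }
        manifest["stages"].append("inputs")

        # ---- stage: masks --------------------------------------------------
        stage = "masks"
        vessel_union = labels.vessel_mask()
        artery, vein = split_by_label(vessel_union, labels)
        artery_gm = restrict_to_gm(artery, gm)
        vein_gm = restrict_to_gm(vein, gm)
        shells = {
            "artery": make_shells(
                artery, config.K, config.connectivity, brain=brain, exclude=vessel_union
            ),
            "vein": make_shells(
                vein, config.K, config.connectivity, brain=brain, exclude=vessel_union
            ),
        }
        manifest["masks"] = {
            "artery_voxels": artery.n_true,
            "vein_voxels": vein.n_true,
            "artery_gm_voxels": artery_gm.n_true,
            "vein_gm_voxels": vein_gm.n_true,
            "gm_voxels": gm.n_true,
            "shell_voxels": {
                t: [s.shell(d).n_true for d in range(1, config.K + 1)]
                for t, s in shells.items()
            },
            "label_convention": {"background": 0, "artery": 1, "vein": 2},
        }
        manifest["stages"].append("masks")

        # ---- stage: preprocess ---------------------------------------------
        stage = "preprocess"
        clean, prov = preprocess_bold(
            bold, wm, csf, band=tuple(config.band), fwhm_mm=config.fwhm_mm
        )
        manifest["preprocess"] = prov
        manifest["stages"].append("preprocess")

        # ---- stage: connectivity -------------------------------------------
        stage = "connectivity"
        vascular = category_metrics(
            clean, artery, vein, gm,
            threshold=config.threshold, mode=config.mode, block_size=config.block_size,
            categories=("VV", "AA", "AV", "VA"),
        )
        # GM-restricted vessels for the macrovascular-to-GM ratios
        gm_restricted = category_metrics(
            clean, artery_gm, vein_gm, gm,
            threshold=config.threshold, mode=config.mode, block_size=config.block_size,
        )
        ratios = {
            "VV:V_GM": ratio_maps(gm_restricted["VV"], gm_restricted["V_GM"]),
            "VA:V_GM": ratio_maps(gm_restricted["VA"], gm_restricted["V_GM"]),
            "AV:A_GM": ratio_maps(gm_restricted["AV"], gm_restricted["A_GM"]),
            "AA:A_GM": ratio_maps(gm_restricted["AA"], gm_restricted["A_GM"]),
        }
        manifest["stages"].append("connectivity")

        # ---- stage: perivascular -------------------------------------------
        stage = "perivascular"
        profiles = {
            "artery": shell_metrics(
                clean, shells["artery"], artery, gm,
                threshold=config.threshold, mode=config.mode, vessel_type="artery",
                block_size=config.block_size,
            ),
            "vein": shell_metrics(
                clean, shells["vein"], vein, gm,
                threshold=config.threshold, mode=config.mode, vessel_type="vein",
                block_size=config.block_size,
            ),
        }
        shell_overlap = {}
        for d in range(1, config.K + 1):
            a = shells["artery"].shell(d)
            v = shells["vein"].shell(d)
            inter = a.intersect(v).n_true
            denom = max(a.union(v).n_true, 1)
            shell_overlap[d] = inter / denom
        manifest["perivascular"] = {"shell_overlap_fraction": shell_overlap}
        manifest["stages"].append("perivascular")

        # ---- stage: occupancy (optional) -----------------------------------
        occ_df = None
        if config.occupancy is not None:
            stage = "occupancy"
            import nibabel as nib

            occ = config.occupancy
            freq = np.asanyarray(nib.load(str(occ["freq"])).dataobj)
            rsn_maps = {}
            rsn_spec = occ.get("rsn")
            if isinstance(rsn_spec, dict):
                for name, p in rsn_spec.items():
                    rsn_maps[name] = np.asanyarray(nib.load(str(p)).dataobj)
            elif rsn_spec is not None:
                for p in sorted(Path(rsn_spec).glob("*.nii*")):
                    rsn_maps[p.name.split(".nii")[0]] = np.asanyarray(
                        nib.load(str(p)).dataobj
                    )
            if not rsn_maps:
                raise ValueError("occupancy config produced no RSN maps")
            occ_df = occupancy_table(
                rsn_maps, freq,
                z_thresh=occ.get("z", 3.0), pct_thresh=occ.get("pct", 90.0),
            )
            manifest["stages"].append("occupancy")

        # ---- stage: outputs ------------------------------------------------
        stage = "outputs"
        _save_maps(vascular, out, "vascular_", manifest["files"])
        _save_maps(gm_restricted, out, "gmres_", manifest["files"])
        _save_maps(ratios, out, "ratio_", manifest["files"])

        session_maps: dict = {}
        session_maps.update(vascular)
        session_maps.update({f"gmres_{k}": v for k, v in gm_restricted.items()})
        session_maps.update(ratios)
        summary = group_summarize([session_maps])
        _write_tsv(summary.per_session, out / "session_summary.tsv")
        manifest["files"].append("session_summary.tsv")

        profile_table = pd.concat(
            [profiles["artery"].table, profiles["vein"].table], ignore_index=True
        )
        _write_tsv(profile_table, out / "shell_profiles.tsv")
        manifest["files"].append("shell_profiles.tsv")

        hist_rows: list[dict] = []
        for cat, m in session_maps.items():
            hist_rows.extend(_histogram_rows(cat, m))
        _write_tsv(pd.DataFrame(hist_rows), out / "histograms.tsv")
        manifest["files"].append("histograms.tsv")
        (out / "histogram_edges.json").write_text(
            json.dumps({k: list(map(float, v)) for k, v in _HIST_EDGES.items()}, indent=2)
        )
        manifest["files"].append("histogram_edges.json")

        if occ_df is not None:
            _write_tsv(occ_df, out / "rsn_occupancy.tsv")
            manifest["files"].append("rsn_occupancy.tsv")

        manifest["stages"].append("outputs")
        manifest["status"] = "complete"
    except (ConfigError,):
        raise
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise StageError(stage, e) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
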