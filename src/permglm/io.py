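"""Readers, writers and run configuration for the command-line tool.

Tabular inputs are plain text, headerless by default, with the delimiter
sniffed between tab and comma.  Image inputs (NIfTI) are flattened to an
N x V matrix over a mask of voxels with nonzero variance; outputs are
written back into the same grid as 1 - p maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Contrast, DesignMatrix
from .inference import InferenceResult
from .shuffling import ExchangeabilityBlocks
from .statistic import VarianceGroups

__all__ = ["RunConfig", "read_table", "read_inputs", "write_outputs"]

_IMAGE_SUFFIXES = (".nii", ".nii.gz")


@dataclass
class RunConfig:
    """Everything a `permglm run` invocation needs."""

    data: str
    design: str
    contrast: str
    output: str
    blocks: str | None = None
    block_mode: str = "within"
    vg: str | None = None
    method: str = "freedman_lane"
    stat: str = "auto"
    regime: str = "ee"
    n_shufflings: int = 1000
    alpha: float = 0.05
    seed: int | None = None
    header: bool = False
    dedup_cmc: bool = False
    save_null: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_shufflings < 1:
            raise ValueError("need at least one shuffling")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _is_image(path: str) -> bool:
    return any(str(path).endswith(sfx) for sfx in _IMAGE_SUFFIXES)


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def read_table(path: str, header: bool = False) -> np.ndarray:
    """Read a numeric TSV/CSV into a float matrix (rows = observations)."""
    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=_sniff_sep(path), header=0 if header else None)
    arr = df.to_numpy()
    try:
        arr = arr.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return arr


def _read_labels(path: str, N: int, what: str) -> np.ndarray:
    arr = read_table(path)
    if arr.ndim != 2 or arr.shape[1] != 1:
        raise ValueError(f"{what} file {path} must be a single column")
    if arr.shape[0] != N:
        raise ValueError(
            f"{what} file {path} has {arr.shape[0]} rows, expected {N}"
        )
    return arr[:, 0].astype(int)


def _load_image(path: str):
    import nibabel as nib

    img = nib.load(path)
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"image {path} must be 4-D (space x observations)")
    flat = vol.reshape(-1, vol.shape[-1]).T  # N x all-voxels
    mask = flat.std(axis=0) > 0
    return flat[:, mask], {"mask": mask, "shape": vol.shape[:3], "affine": img.affine}


def read_inputs(config: RunConfig):
    """Load and cross-validate all inputs of a run.

    Returns ``(Y, design, contrast, blocks, vg, image_info)`` where
    ``image_info`` is None for tabular data.
    """
    image_info = None
    if _is_image(config.data):
        Y, image_info = _load_image(config.data)
    else:
        Y = read_table(config.data, header=config.header)
    design = DesignMatrix(read_table(config.design, header=config.header))
    contrast = Contrast(read_table(config.contrast, header=config.header))
    N = Y.shape[0]
    if design.N != N:
        raise ValueError(
            f"data {config.data} has {N} rows but design "
            f"{config.design} has {design.N}"
        )
    if contrast.C.shape[0] != design.r:
        raise ValueError(
            f"contrast {config.contrast} has {contrast.C.shape[0]} rows but "
            f"the design has {design.r} regressors"
        )
    blocks = None
    if config.blocks is not None:
        blocks = ExchangeabilityBlocks(
            _read_labels(config.blocks, N, "exchangeability-block"),
            mode=config.block_mode,
        )
    vg = None
    if config.vg is not None:
        vg = VarianceGroups(_read_labels(config.vg, N, "variance-group"))
    return Y, design, contrast, blocks, vg, image_info


def _write_image(path: str, values: np.ndarray, image_info: dict) -> None:
    import nibabel as nib

    full = np.zeros(int(np.prod(image_info["shape"])))
    full[image_info["mask"]] = values
    nib.save(
        nib.Nifti1Image(
            full.reshape(image_info["shape"]).astype(np.float32),
            image_info["affine"],
        ),
        path,
    )


def write_outputs(
    result: InferenceResult,
    config: RunConfig,
    *,
    Tmax: np.ndarray | None = None,
    image_info: dict | None = None,
    log: dict | None = None,
) -> list[str]:
    """Write the per-test table, optional null distribution, image maps and
    the run log.  Returns the list of files written."""
    prefix = config.output
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    written = []
    table = pd.DataFrame(
        {
            "index": np.arange(result.T0.size),
            "T0": result.T0,
            "p_unc": result.p_unc,
            "p_fwer": result.p_fwer,
            "p_fdr": result.p_fdr,
            "sig_unc": 1.0 - result.p_unc,
            "sig_fwer": 1.0 - result.p_fwer,
        }
    )
    out = f"{prefix}_results.tsv"
    table.to_csv(out, sep="\t", index=False, float_format="%.12g")
    written.append(out)
    if config.save_null and Tmax is not None:
        out = f"{prefix}_tmax.tsv"
        pd.DataFrame({"Tmax": Tmax}).to_csv(
            out, sep="\t", index=False, float_format="%.12g"
        )
        written.append(out)
    if image_info is not None:
        for name, vals in (
            ("sig_unc", 1.0 - result.p_unc),
            ("sig_fwer", 1.0 - result.p_fwer),
            ("stat", result.T0),
        ):
            out = f"{prefix}_{name}.nii.gz"
            _write_image(out, vals, image_info)
            written.append(out)
    logpath = f"{prefix}_log.json"
    payload = {
        "config": {
            k: v for k, v in vars(config).items() if not isinstance(v, dict)
        },
        "J": result.J,
        "fwer_thresholds": result.fwer_thresholds,
    }
    if log:
        payload.update(log)
    with open(logpath, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
    written.append(logpath)
    return written
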