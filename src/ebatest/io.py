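"""Config parsing, data reading and result serialization.

Model configs are YAML mappings of factors to indicator names plus
identification options; data files are delimited text with a header row
and an optional group column; results round-trip through delimited text
with p values at full double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import CfaModelSpec

VALID_METHODS = (
    "ML", "RLS", "ALL", "pEBA2", "pEBA4", "pEBA6", "pEBAdf", "pOLS2",
    "SB", "SS", "SF", "SB_2001",
)
RESULT_COLUMNS = ("label", "procedure", "base", "gamma_variant",
                  "statistic", "df", "p_value", "flags")


@dataclass
class RunConfig:
    mode: str  # gof | nested | study
    data: str | None = None
    group_col: str | None = None
    model: str | None = None
    model_m0: str | None = None
    model_m1: str | None = None
    methods: list = field(default_factory=list)
    gamma_variants: tuple = ("biased", "unbiased")
    ud_method: str = "2000"
    seed: int = 0
    out: str | None = None


def split_method_label(label: str) -> tuple[str, str, str]:
    """'pEBA4_RLS_UG' -> (method, base, gamma_variant)."""
    base, variant = "T_ML", "biased"
    name = label
    if name.endswith("_UG"):
        variant = "unbiased"
        name = name[:-3]
    if name.endswith("_RLS") and name != "RLS":
        base = "T_RLS"
        name = name[:-4]
    if name not in VALID_METHODS:
        raise ValueError(
            f"unknown method {label!r}; valid procedure names are "
            f"{', '.join(VALID_METHODS)} with optional _RLS / _UG suffixes"
        )
    return name, base, variant


def parse_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "mode" not in raw:
        raise ValueError("config must be a mapping with a 'mode' key")
    mode = raw["mode"]
    if mode not in ("gof", "nested", "study"):
        raise ValueError(f"unknown mode {mode!r}")
    defaults = {"gof": ["pEBA4_RLS"], "nested": ["pEBAdf_UG"]}
    methods = raw.get("methods") or defaults.get(mode, [])
    for m in methods:
        split_method_label(m)
    cfg = RunConfig(
        mode=mode,
        data=raw.get("data"),
        group_col=raw.get("group_col"),
        model=raw.get("model"),
        model_m0=raw.get("model_m0"),
        model_m1=raw.get("model_m1"),
        methods=list(methods),
        ud_method=str(raw.get("ud_method", "2000")),
        seed=int(raw.get("seed", 0)),
        out=raw.get("out"),
    )
    if cfg.ud_method not in ("2000", "2001"):
        raise ValueError("ud_method must be '2000' or '2001'")
    return cfg


def read_model_config(path, n_groups: int = 1) -> CfaModelSpec:
    """Build a spec from a YAML factor -> indicators mapping.

    Keys: ``factors`` (mapping), ``variables`` (column order), optional
    ``std_lv`` (fix factor variances at 1; default true), optional
    ``equal_loadings`` (share loadings across groups).
    """
    raw = yaml.safe_load(Path(path).read_text())
    factors = raw["factors"]
    variables = raw.get("variables")
    if variables is None:
        variables = [v for inds in factors.values() for v in inds]
    std_lv = bool(raw.get("std_lv", True))
    equal_loadings = bool(raw.get("equal_loadings", False))
    p, l = len(variables), len(factors)
    vidx = {v: i for i, v in enumerate(variables)}
    fnames = list(factors)
    Ls, Ps, Rs = [], [], []
    for g in range(1, n_groups + 1):
        tag = "" if (equal_loadings or n_groups == 1) else f".g{g}"
        L = np.full((p, l), 0.0, dtype=object)
        for j, fname in enumerate(fnames):
            for k, v in enumerate(factors[fname]):
                if std_lv or k > 0:
                    L[vidx[v], j] = f"l.{fname}.{v}{tag}"
                else:
                    L[vidx[v], j] = 1.0
        P = np.empty((l, l), dtype=object)
        for i in range(l):
            for j in range(l):
                if i == j:
                    P[i, j] = 1.0 if std_lv else f"phi.{fnames[i]}.g{g}"
                else:
                    a, b = sorted((fnames[i], fnames[j]))
                    P[i, j] = f"phi.{a}.{b}.g{g}"
        R = np.full((p, p), 0.0, dtype=object)
        for v in variables:
            R[vidx[v], vidx[v]] = f"psi.{v}.g{g}"
        Ls.append(L)
        Ps.append(P)
        Rs.append(R)
    return CfaModelSpec(Ls, Ps, Rs)


def read_data(path, group_col: str | None = None):
    """Delimited text -> list of per-group n x p arrays (+ column names)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if group_col is None:
        return [df.to_numpy(dtype=float)], list(df.columns)
    cols = [c for c in df.columns if c != group_col]
    groups = sorted(df[group_col].unique())
    data = [df.loc[df[group_col] == g, cols].to_numpy(dtype=float)
            for g in groups]
    return data, cols


def write_results(frame: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if metadata:
            for k, v in metadata.items():
                fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")
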