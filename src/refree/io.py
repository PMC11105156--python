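"""Readers and writers for the package's plain-text table formats.

Two formats are defined: the *variant-class table* (one row per protein/RE
complex: genotype, re, cls[, fluorescence]) and the *long-format coefficient
table* (effect_type, order, sites, states, value) with thresholds and
provenance carried in ``# key=value`` header lines.  Coefficient files are
written in the fixed alphabet enumeration order, so identical tables
serialize byte-for-byte identically.
"""

from __future__ import annotations

import io as _io
import json
import numpy as np
import pandas as pd

from .model import CLASSES, CoefficientTable, RESPONSE_ELEMENTS
from .sequence_space import InputError

FORMAT_VERSION = 1


def read_variant_classes(path) -> pd.DataFrame:
    """Read and validate a comma-separated variant-class table.

    Errors (unknown symbol, unknown class, duplicate complex) name the
    offending line number.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"genotype", "re", "cls"}
    if not required <= set(df.columns):
        raise InputError(
            f"variant-class table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    lines = df.index + 2  # header is line 1
    for col, allowed in (("re", set(RESPONSE_ELEMENTS)), ("cls", set(CLASSES))):
        bad = ~df[col].isin(allowed)
        if bad.any():
            ln = int(lines[bad][0])
            raise InputError(
                f"line {ln}: unknown {col} label {df[col][bad].iloc[0]!r}"
            )
    n_sites = len(df["genotype"].iloc[0])
    symbols = df["genotype"].str.len() != n_sites
    if symbols.any():
        ln = int(lines[symbols][0])
        raise InputError(f"line {ln}: inconsistent genotype length")
    dup = df.duplicated(subset=["genotype", "re"])
    if dup.any():
        ln = int(lines[dup][0])
        raise InputError(
            f"line {ln}: duplicate complex "
            f"({df['genotype'][dup].iloc[0]}, {df['re'][dup].iloc[0]})"
        )
    return df


def write_variant_classes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_coefficients(
    coeffs: CoefficientTable, path, metadata: dict | None = None
) -> None:
    """Write a long-format coefficient table with a provenance header."""
    meta = {
        "format_version": FORMAT_VERSION,
        "alphabet": "".join(coeffs.alphabet),
        "n_sites": coeffs.n_sites,
        "max_order": coeffs.max_order,
        "theta_nw": coeffs.theta_nw,
        "theta_ws": coeffs.theta_ws,
        "link_scale": coeffs.link_scale,
        "is_recentered": coeffs.is_recentered,
        "lam": coeffs.lam,
    }
    if metadata:
        meta.update(metadata)
    buf = _io.StringIO()
    for key, value in meta.items():
        buf.write(f"# {key}={json.dumps(value)}\n")
    buf.write("effect_type,order,sites,states,value\n")
    for key, value in coeffs.items():
        sites = "".join(map(str, key.sites))
        states = "".join(key.states)
        buf.write(f"{key.effect_type},{key.order},{sites},{states},{value!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_coefficients(path, expected_alphabet: str | None = None) -> CoefficientTable:
    """Read a long-format coefficient table; refuses alphabet mismatches."""
    meta: dict = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                k, _, v = line[2:].rstrip("\n").partition("=")
                meta[k] = json.loads(v)
            else:
                rows.append(line)
    if meta.get("format_version") != FORMAT_VERSION:
        raise InputError(
            f"unsupported coefficient-file version {meta.get('format_version')!r}"
        )
    alphabet = tuple(meta["alphabet"])
    if expected_alphabet is not None and "".join(alphabet) != expected_alphabet:
        raise InputError(
            "coefficient file alphabet "
            f"{meta['alphabet']!r} does not match expected "
            f"{expected_alphabet!r}"
        )
    df = pd.read_csv(
        _io.StringIO("".join(rows)),
        dtype={"effect_type": str, "order": int, "sites": str, "states": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    table = CoefficientTable.zeros(
        alphabet,
        int(meta["n_sites"]),
        int(meta["max_order"]),
        float(meta["theta_nw"]),
        float(meta["theta_ws"]),
    )
    table.link_scale = float(meta["link_scale"])
    table.is_recentered = bool(meta["is_recentered"])
    table.lam = meta.get("lam")
    index = {s: i for i, s in enumerate(alphabet)}
    for (etype, sites_str), sub in df.groupby(
        ["effect_type", "sites"], sort=False
    ):
        sites0 = (
            tuple(int(ch) - 1 for ch in str(sites_str)) if sites_str else ()
        )
        if not sites0:
            table.tables[(etype, ())] = np.asarray(
                float(sub["value"].iloc[0])
            )
            continue
        arr = table.tables[(etype, sites0)]
        codes = np.array(
            [[index[s] for s in st] for st in sub["states"]], dtype=np.int64
        )
        arr[tuple(codes[:, k] for k in range(codes.shape[1]))] = (
            sub["value"].astype(float).to_numpy()
        )
    return table
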