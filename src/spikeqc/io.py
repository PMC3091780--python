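"""Tab-delimited readers/writers for designs, intensity and Ct tables.

All files are UTF-8 TSV with one header line, ``.`` decimal points and no
thousands separators.  Failed qPCR reactions are serialised as the literal
token ``UNDETERMINED`` (parsed case-insensitively) — never as a sentinel
number.  Readers validate schema, uniqueness and value ranges and report
the offending line number on error.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import DesignError, PanelDesign, PanelPair, RNAStandard, make_condition_panels
from .simulate import BLANK

__all__ = [
    "ParseError",
    "read_intensity_table",
    "write_intensity_table",
    "read_ct_table",
    "write_ct_table",
    "read_design",
    "write_design",
    "write_design_wide",
    "read_truth",
    "write_truth",
]

UNDETERMINED = "UNDETERMINED"

INTENSITY_COLUMNS = [
    "feature_id",
    "standard_id",
    "replicate_probe_index",
    "blank",
    "array_id",
    "sample",
    "run",
    "labelling_id",
    "raw_intensity",
]
CT_FILE_COLUMNS = ["assay_id", "sample", "run", "replicate", "ct"]


class ParseError(ValueError):
    """Malformed input file; the message carries the path and line number."""


def _rows(path: str | Path, expected_header: list[str]):
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if header != expected_header:
            raise ParseError(
                f"{path}:1: header {header!r} does not match schema {expected_header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(expected_header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(expected_header)} fields, got {len(row)}"
                )
            yield lineno, row


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format intensity TSV (schema in ``INTENSITY_COLUMNS``).

    ``standard_id == BLANK`` rows are mapped to the blank flag; duplicate
    (feature_id, array_id) keys and negative intensities are rejected with
    their line number.
    """
    recs, seen = [], set()
    for lineno, row in _rows(path, INTENSITY_COLUMNS):
        fid, sid, rpi, blank, aid, sample, run, lab, raw = row
        key = (fid, aid)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate (feature_id, array_id) {key}")
        seen.add(key)
        try:
            rpi_i = int(rpi)
            run_i = int(run)
            raw_f = float(raw)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if raw_f < 0:
            raise ParseError(f"{path}:{lineno}: negative raw_intensity {raw_f}")
        blank_b = blank.strip().lower() in ("true", "1", "yes")
        if sid == BLANK:
            blank_b = True
        recs.append((fid, sid, rpi_i, blank_b, aid, sample, run_i, lab, raw_f))
    return pd.DataFrame(recs, columns=INTENSITY_COLUMNS)


def write_intensity_table(table: pd.DataFrame, path: str | Path) -> None:
    table[INTENSITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path, max_cycles: int = 45) -> pd.DataFrame:
    """Read a Ct TSV; the token ``UNDETERMINED`` marks failed reactions.

    Determined Ct values must lie in (0, max_cycles]; duplicated
    (assay, sample, run, replicate) keys are rejected.
    """
    recs, seen = [], set()
    for lineno, row in _rows(path, CT_FILE_COLUMNS):
        aid, sample, run, rep, ct = row
        try:
            run_i, rep_i = int(run), int(rep)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        key = (aid, sample, run_i, rep_i)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate reaction key {key}")
        seen.add(key)
        if ct.strip().upper() == UNDETERMINED:
            recs.append((aid, sample, run_i, rep_i, np.nan, False))
            continue
        try:
            ct_f = float(ct)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: ct must be a number or {UNDETERMINED!r} (got {ct!r})"
            ) from None
        if not 0 < ct_f <= max_cycles:
            raise ParseError(
                f"{path}:{lineno}: ct {ct_f} outside (0, {max_cycles}]"
            )
        recs.append((aid, sample, run_i, rep_i, ct_f, True))
    return pd.DataFrame(
        recs, columns=["assay_id", "sample", "run", "replicate", "ct", "determined"]
    )


def write_ct_table(cts: pd.DataFrame, path: str | Path) -> None:
    out = cts.copy()
    out["ct"] = [
        UNDETERMINED if not d else repr(float(c))
        for c, d in zip(out["ct"], out["determined"])
    ]
    out[CT_FILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path, lengths: dict[str, int] | None = None) -> PanelDesign:
    """Read a long-format design TSV (standard, sample, copies_per_ng)."""
    recs = []
    for lineno, row in _rows(path, ["standard", "sample", "copies_per_ng"]):
        std, sample, copies = row
        try:
            c = float(copies)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if c < 0:
            raise ParseError(f"{path}:{lineno}: negative copies_per_ng")
        recs.append((std, sample, c))
    df = pd.DataFrame(recs, columns=["standard", "sample", "copies_per_ng"])
    if df.duplicated(["standard", "sample"]).any():
        raise ParseError(f"{path}: duplicate (standard, sample) rows")
    wide = df.pivot(index="standard", columns="sample", values="copies_per_ng")
    if wide.isna().any().any():
        raise ParseError(f"{path}: incomplete standard x sample grid")
    std_order = list(dict.fromkeys(df["standard"]))
    sample_order = list(dict.fromkeys(df["sample"]))
    standards = [
        RNAStandard(s, (lengths or {}).get(s, 1000)) for s in std_order
    ]
    try:
        return PanelDesign(
            standards=standards, samples=sample_order, copies=wide.loc[std_order, sample_order]
        )
    except DesignError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_design(design: PanelDesign, path: str | Path) -> None:
    design.to_long().to_csv(path, sep="\t", index=False, header=["standard", "sample", "copies_per_ng"])


def write_design_wide(design: PanelDesign, path: str | Path) -> None:
    """Wide-format writer matching the published pool-table layout
    (standards as rows, samples as columns)."""
    design.copies.rename_axis("standard").to_csv(path, sep="\t")


def read_truth(path: str | Path) -> PanelPair:
    """Read a truth TSV (standard, copies_A, copies_B, expected_fc)."""
    a, b = {}, {}
    for lineno, row in _rows(path, ["standard", "copies_A", "copies_B", "expected_fc"]):
        std, ca, cb, fc = row
        try:
            ca_f, cb_f, fc_f = float(ca), float(cb), float(fc)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if ca_f > 0 and abs(cb_f / ca_f - fc_f) > 1e-9 * max(1.0, abs(fc_f)):
            raise ParseError(
                f"{path}:{lineno}: expected_fc {fc_f} inconsistent with copies {ca_f}, {cb_f}"
            )
        a[std], b[std] = ca_f, cb_f
    try:
        return make_condition_panels(a, b)
    except DesignError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_truth(pair: PanelPair, path: str | Path) -> None:
    pair.truth_frame().to_csv(path, sep="\t", index=False)
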