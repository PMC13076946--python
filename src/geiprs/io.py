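"""File formats: PLINK bed/bim/fam, sample-keyed TSV tables, coefficient
and score files, and the simulation-truth JSON sidecar.

The PLINK .bed codec implements the SNP-major two-bit encoding directly
(00 = homozygous A1 -> dosage 2, 01 = missing, 10 = heterozygous -> 1,
11 = homozygous A2 -> 0); the counted allele is bim A1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> dosage; -1 marks missing
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}

MISSING = -1


def write_plink(
    prefix: str | Path,
    dosages: np.ndarray,
    variant_ids: list[str] | None = None,
    sample_ids: list[tuple[str, str]] | None = None,
) -> None:
    """Write dosage hard-calls (n x p, entries {0,1,2} or -1 missing) as a
    bed/bim/fam triplet.  Variants get placeholder chromosome/position and
    A1/A2 alleles A/B; the counted (A1) allele is the dosage allele."""
    prefix = Path(prefix)
    dosages = np.asarray(dosages)
    n, p = dosages.shape
    if variant_ids is None:
        variant_ids = [f"snp{j + 1}" for j in range(p)]
    if sample_ids is None:
        sample_ids = [(f"F{i + 1}", f"I{i + 1}") for i in range(n)]
    if len(variant_ids) != p or len(sample_ids) != n:
        raise FormatError("variant/sample id lengths do not match the dosage matrix")

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        n_bytes = (n + 3) // 4
        for j in range(p):
            packed = bytearray(n_bytes)
            col = dosages[:, j]
            for i in range(n):
                code = _DOSAGE_TO_CODE.get(int(col[i]))
                if code is None:
                    raise FormatError(f"dosage {col[i]} at ({i}, {j}) not in {{0,1,2,-1}}")
                packed[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(packed))

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, vid in enumerate(variant_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for fid, iid in sample_ids:
            fh.write(f"{fid}\t{iid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str | Path) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Read a bed/bim/fam triplet.

    Returns (dosages, variant_ids, sample_ids) with dosages n x p in
    {0, 1, 2} and -1 for missing; rows follow fam order, columns bim order.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"id": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype={"fid": str, "iid": str},
    )
    n, p = len(fam), len(bim)
    if n == 0:
        raise FormatError("empty fam file")
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"bad .bed magic {raw[:3].hex()}; expected SNP-major 6c1b01"
        )
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if payload.size != n_bytes * p:
        raise FormatError(
            f".bed payload has {payload.size} bytes; expected {n_bytes * p} "
            f"for {n} samples x {p} variants"
        )
    mat = payload.reshape(p, n_bytes)
    # unpack two-bit codes, low bits first within each byte
    codes = np.stack(
        [(mat >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(p, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    sample_ids = list(zip(fam["fid"], fam["iid"]))
    return dosages, list(bim["id"]), sample_ids


def read_table(
    path: str | Path,
    sample_ids: list[tuple[str, str]],
    required: list[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Read a `FID IID ...` TSV and align rows to fam sample order.

    Returns the aligned table (indexed by (FID, IID)) and the list of fam
    samples missing from the table (dropped from analysis).
    """
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    for col in ("FID", "IID") + tuple(required or ()):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    if df.duplicated(subset=["FID", "IID"]).any():
        dup = df[df.duplicated(subset=["FID", "IID"])].iloc[0]
        raise FormatError(f"duplicate sample ({dup['FID']}, {dup['IID']}) in {path}")
    df = df.set_index(["FID", "IID"])
    unmatched = [sid for sid in sample_ids if sid not in df.index]
    kept = [sid for sid in sample_ids if sid in df.index]
    return df.loc[kept], unmatched


def write_coefficients(
    path: str | Path,
    variant_ids: list[str],
    beta_g: np.ndarray,
    beta_gei: np.ndarray,
    dense: bool = False,
) -> None:
    """Coefficient TSV `variant_id beta_G beta_GEI`; zero rows only with dense."""
    with open(path, "w") as fh:
        fh.write("variant_id\tbeta_G\tbeta_GEI\n")
        for vid, bg, bi in zip(variant_ids, beta_g, beta_gei):
            if dense or bg != 0.0 or bi != 0.0:
                fh.write(f"{vid}\t{float(bg)!r}\t{float(bi)!r}\n")


def read_coefficients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    for col in ("variant_id", "beta_G", "beta_GEI"):
        if col not in df.columns:
            raise FormatError(f"coefficient file missing column {col!r}")
    return df


def write_scores(
    path: str | Path,
    sample_ids: list[tuple[str, str]],
    prs_g: np.ndarray,
    prs_gei: np.ndarray,
) -> None:
    """Score TSV `FID IID PRS_G PRS_GEI`."""
    with open(path, "w") as fh:
        fh.write("FID\tIID\tPRS_G\tPRS_GEI\n")
        for (fid, iid), a, b in zip(sample_ids, prs_g, prs_gei):
            fh.write(f"{fid}\t{iid}\t{float(a)!r}\t{float(b)!r}\n")


def write_truth_sidecar(path: str | Path, truth) -> None:
    """JSON sidecar with simulation ground-truth indices, weights and
    standardization constants (matrices live in the PLINK/TSV files)."""
    cfg = truth.config
    payload = {
        "causal_main_idx": truth.causal_main_idx.tolist(),
        "causal_gei_idx": truth.causal_gei_idx.tolist(),
        "true_beta_g": truth.true_beta_g.tolist(),
        "true_beta_gei": truth.true_beta_gei.tolist(),
        "component_weights": dict(cfg.component_weights) if cfg else None,
        "standardization": {k: list(v) for k, v in truth.standardization.items()},
        "seed": cfg.seed if cfg else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
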