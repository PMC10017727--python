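"""Cohort-file interfaces: severity staging, additive genotype coding,
feature-table round-tripping, subject alignment across files, optional PLINK
``.raw`` import, and reproducibility manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "stage_from_hamd",
    "code_genotype_additive",
    "read_feature_table",
    "write_feature_table",
    "align_subjects",
    "read_plink_raw",
    "aal116_names",
    "write_manifest",
]

#: subjects scoring in the 9-19 band fall between the control ceiling and the
#: moderate-depression floor and are excluded from staging
UNCLASSIFIED = "unclassified"


def stage_from_hamd(score: int) -> str:
    """Diagnosis stage from a 24-item Hamilton depression score.

    <= 8 is a healthy control, 20-34 moderate depression, >= 35 severe
    depression.  Scores of 9-19 fall in the gap between those clinical
    definitions and are returned as ``unclassified`` (callers should drop
    such subjects, with a warning).
    """
    if score < 0:
        raise ValueError(f"HAM-D24 score must be nonnegative, got {score}")
    if score <= 8:
        return "HC"
    if 20 <= score <= 34:
        return "MD"
    if score >= 35:
        return "SD"
    logger.warning("HAM-D24 score %d falls in the unclassified 9-19 band", score)
    return UNCLASSIFIED


def code_genotype_additive(
    calls: Sequence[str], missing: str = "./."
) -> tuple[np.ndarray, dict]:
    """Additive 0/1/2 coding of one SNP's per-subject allele pairs.

    Allele frequencies are computed from the sample; the major allele codes
    as 0, the heterozygote as 1, the minor homozygote as 2.  Calls like
    ``"A/C"`` or ``"AC"`` are accepted; missing calls code as NaN and a flag.
    A 50/50 frequency tie takes the lexicographically smaller allele as
    major (deterministic; logged).

    Returns the code vector and a report dict with alleles, frequencies,
    missing indices and a monomorphic flag.
    """
    parsed: list[tuple[str, str] | None] = []
    for call in calls:
        c = str(call).strip()
        if c in (missing, "", "NA", "nan", "--", "00", "0/0"):
            parsed.append(None)
            continue
        alleles = c.split("/") if "/" in c else list(c)
        if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
            raise ValueError(f"cannot parse genotype call {call!r}")
        parsed.append((alleles[0].upper(), alleles[1].upper()))
    observed = [a for p in parsed if p is not None for a in p]
    if not observed:
        raise ValueError("all genotype calls are missing")
    counts = pd.Series(observed).value_counts()
    if len(counts) > 2:
        raise ValueError(f"more than two alleles observed: {sorted(counts.index)}")
    if len(counts) == 1:
        major = minor = counts.index[0]
        logger.warning("monomorphic SNP: only allele %s observed", major)
    else:
        a, b = sorted(counts.index)
        if counts[a] == counts[b]:
            major, minor = a, b
            logger.info("allele-frequency tie: taking %s as major (lexicographic)", a)
        else:
            major = counts.idxmax()
            minor = counts.idxmin()
    codes = np.full(len(parsed), np.nan)
    for i, p in enumerate(parsed):
        if p is None:
            continue
        codes[i] = sum(1 for a in p if a == minor) if major != minor else 0
    missing_idx = [i for i, p in enumerate(parsed) if p is None]
    if missing_idx:
        logger.warning("%d missing genotype call(s) coded as NaN", len(missing_idx))
    report = {
        "major": major,
        "minor": minor,
        "freq_major": float(counts.get(major, 0) / counts.sum()),
        "missing": missing_idx,
        "monomorphic": major == minor or len(counts) == 1,
    }
    return codes, report


def write_feature_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write an N x d feature table as TSV (subject_id index, ROI columns).

    Values are serialized with 17 significant digits so that a read-back
    reproduces them bit-for-bit.
    """
    table = table.copy()
    table.index.name = "subject_id"
    table.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`.

    The first column must be ``subject_id`` with unique entries; the body
    must be numeric.  Errors name the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject id(s) in {path}: {dups}")
    if df.columns.duplicated().any():
        raise ValueError(f"duplicate column name(s) in {path}")
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            # float() is correctly rounding, so 17-digit text round-trips
            out[col] = df[col].map(float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric cell in {path} at row {bad!r}, column {col!r}"
            ) from None
    return out


def align_subjects(tables: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Intersect several subject-indexed tables on their common subjects.

    Feature tables (same column sets) must agree on column names; dropped
    subjects are logged per table.  Returns the aligned tables in the same
    key order, all with an identical subject index.
    """
    if not tables:
        raise ValueError("no tables to align")
    keys = list(tables)
    common = tables[keys[0]].index
    for key in keys[1:]:
        common = common.intersection(tables[key].index)
    if len(common) == 0:
        raise ValueError("no subjects common to all tables")
    common = sorted(common)
    aligned = {}
    for key in keys:
        dropped = set(tables[key].index) - set(common)
        if dropped:
            logger.warning("alignment dropped %d subject(s) from %r: %s",
                           len(dropped), key, sorted(dropped))
        aligned[key] = tables[key].loc[common]
    col_sets = {}
    for key, df in aligned.items():
        col_sets.setdefault(frozenset(df.columns), []).append(key)
    for cols, members in col_sets.items():
        ref = aligned[members[0]].columns
        for key in members[1:]:
            if list(aligned[key].columns) != list(ref):
                raise ValueError(
                    f"column order differs between {members[0]!r} and {key!r}"
                )
    return aligned


def read_plink_raw(path: str | Path) -> pd.DataFrame:
    """Read a PLINK ``--recode A`` (.raw) additive genotype table.

    Returns an IID-indexed DataFrame of 0/1/2 dosages (NaN for missing),
    with the ``_ALLELE`` suffix stripped from SNP column names.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = [c for c in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")
            if c in df.columns]
    if "IID" not in meta:
        raise ValueError(f"{path} lacks an IID column; not a PLINK .raw file?")
    geno = df.drop(columns=meta).apply(pd.to_numeric, errors="coerce")
    geno.index = df["IID"].astype(str)
    geno.columns = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    return geno


def read_nifti_node_features(
    density_path: str | Path,
    atlas_path: str | Path,
    label_map_path: str | Path,
    subject_id: str = "",
):
    """Node features from NIfTI density + atlas volumes and a label-map TSV.

    The label map is a two-column TSV (integer label, ROI name) without
    header.  Volumes must be co-registered; they are compared on array shape
    only.  Requires nibabel.
    """
    import nibabel as nib

    from .features import extract_node_features

    density = np.asanyarray(nib.load(str(density_path)).dataobj, dtype=float)
    atlas = np.rint(
        np.asanyarray(nib.load(str(atlas_path)).dataobj)).astype(int)
    label_map: dict[int, str] = {}
    for line in Path(label_map_path).read_text().strip().splitlines():
        lab, name = line.split("\t")
        label_map[int(lab)] = name
    return extract_node_features(density, atlas, label_map,
                                 subject_id=subject_id)


def aal116_names() -> list[str]:
    """The 116 region names of the AAL atlas, in label order."""
    text = (resources.files("phenet") / "data" / "aal116.tsv").read_text()
    names = []
    for line in text.strip().splitlines():
        _, name = line.split("\t")
        names.append(name)
    return names


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    config: dict,
    seed: int | None,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Write a reproducibility manifest next to a command's outputs.

    Records the command, a stable hash of its configuration, the seed, the
    package version and a sha256 checksum per input file — enough to rerun
    the step bit-for-bit.  Deliberately contains no timestamps so that
    reruns produce identical files.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "command": command,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        # keyed by file name, not path, so reruns in other directories match
        "inputs": {Path(p).name: _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / f"{command}.manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
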