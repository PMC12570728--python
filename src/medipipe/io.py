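"""File formats, probe annotation and reference-table access.

Beta matrices travel as (optionally gzip-compressed) TSV with probe rows
and a header of sample ids; phenotype tables as CSV; ground truth and
decompositions as JSON.  All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import gzip
import json
import os
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CohortTruth, MethylationMatrix

__all__ = [
    "AnnotationRecord",
    "read_beta_matrix",
    "write_beta_matrix",
    "scan_beta_matrix",
    "read_phenotypes",
    "write_phenotypes",
    "write_truth",
    "read_truth",
    "annotate_probes",
    "load_reference_candidate_sets",
    "load_reference_decompositions",
    "atomic_write_text",
]

FLOAT_FORMAT = "%.10g"  # round-trip precision documented at 10 significant digits


@dataclass
class AnnotationRecord:
    probe_id: str
    chromosome: str | None
    position: int | None
    gene: str | None
    gene_region: str | None
    island_relation: str | None
    annotated: bool = True


def atomic_write_text(path, text: str) -> None:
    """Write text atomically: temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_beta_matrix(matrix: MethylationMatrix, path) -> None:
    """Write probes x samples TSV (gzip if the path ends in .gz)."""
    path = Path(path)
    frame = matrix.beta.T  # probes as rows
    text = frame.to_csv(sep="\t", float_format=FLOAT_FORMAT, index_label="probe_id")
    if path.suffix == ".gz":
        path.parent.mkdir(parents=True, exist_ok=True)
        fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
        os.close(fd)
        try:
            # fixed mtime keeps gzip output byte-identical across reruns
            with open(tmp, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as gz:
                gz.write(text.encode())
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
    else:
        atomic_write_text(path, text)


def read_beta_matrix(path) -> MethylationMatrix:
    """Read a probes x samples TSV (optionally gzipped) into a matrix.

    Values are validated into [0, 1]; an out-of-range value raises an
    error naming the probe and sample, and duplicate probe ids raise.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {path}")
    values = frame.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0.0) | (values > 1.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of [0, 1] at probe {frame.index[i]!r}, "
            f"sample {frame.columns[j]!r}: {values[i, j]}"
        )
    out = frame.T
    out.index.name = None
    out.columns.name = None
    return MethylationMatrix(out)


def scan_beta_matrix(path) -> tuple[int, int]:
    """Structural check without parsing values: (n_probes, n_samples).

    Streams the file line by line, verifying only that every row has the
    same number of fields as the header.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline().rstrip("\n")
        n_samples = len(header.split("\t")) - 1
        n_probes = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n_fields = line.count("\t") + 1
            if n_fields != n_samples + 1:
                raise ValueError(
                    f"line {lineno}: expected {n_samples + 1} fields, got {n_fields}"
                )
            n_probes += 1
    return n_probes, n_samples


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    atomic_write_text(path, pheno.to_csv(index=False, float_format=FLOAT_FORMAT))


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(truth: CohortTruth, path) -> None:
    atomic_write_text(path, json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_truth(path) -> CohortTruth:
    with open(path) as fh:
        d = json.load(fh)
    return CohortTruth(
        true_mediator_ids=d["true_mediator_ids"],
        alpha_a=np.asarray(d["alpha_a"]),
        beta_m=np.asarray(d["beta_m"]),
        direct_effect=d["direct_effect"],
        expected_total_effect=d["expected_total_effect"],
        nominal_alpha_a=(
            None if d.get("nominal_alpha_a") is None else np.asarray(d["nominal_alpha_a"])
        ),
    )


def _default_manifest_path():
    return resources.files("medipipe.data") / "probe_annotation.csv"


def annotate_probes(probe_ids, manifest_path=None) -> list[AnnotationRecord]:
    """Look probes up in an annotation manifest.

    The manifest is a CSV with columns probe_id, chromosome, position,
    gene, gene_region, island_relation (positions are 1-based and may
    carry thousands separators).  Unknown probes are returned flagged
    ``annotated=False``, never dropped.
    """
    src = manifest_path if manifest_path is not None else _default_manifest_path()
    try:
        manifest = pd.read_csv(src, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed manifest {src}: {exc}") from exc
    required = {"probe_id", "chromosome", "position"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(required - set(manifest.columns))}")
    if manifest["probe_id"].duplicated().any():
        dup = manifest["probe_id"][manifest["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe id {dup!r} in manifest")

    by_id = manifest.set_index("probe_id")
    records = []
    for pid in probe_ids:
        if pid in by_id.index:
            row = by_id.loc[pid]
            pos_raw = row.get("position")
            try:
                position = int(str(pos_raw).replace(",", "")) if pd.notna(pos_raw) else None
            except ValueError as exc:
                lineno = int(by_id.index.get_loc(pid)) + 2
                raise ValueError(
                    f"malformed position {pos_raw!r} at manifest line {lineno}"
                ) from exc
            if position is not None and position <= 0:
                lineno = int(by_id.index.get_loc(pid)) + 2
                raise ValueError(f"non-positive position at manifest line {lineno}")

            def _opt(key):
                v = row.get(key)
                return None if (v is None or pd.isna(v) or v == "") else str(v)

            records.append(
                AnnotationRecord(
                    probe_id=pid,
                    chromosome=_opt("chromosome"),
                    position=position,
                    gene=_opt("gene"),
                    gene_region=_opt("gene_region"),
                    island_relation=_opt("island_relation"),
                    annotated=True,
                )
            )
        else:
            records.append(
                AnnotationRecord(
                    probe_id=pid,
                    chromosome=None,
                    position=None,
                    gene=None,
                    gene_region=None,
                    island_relation=None,
                    annotated=False,
                )
            )
    return records


def load_reference_candidate_sets() -> dict:
    """Published per-method candidate CpG sets (FDR < 0.05), by exposure."""
    src = resources.files("medipipe.data") / "reference_candidate_sets.json"
    with src.open() as fh:
        data = json.load(fh)
    return {k: v for k, v in data.items() if k != "description"}


def load_reference_decompositions() -> pd.DataFrame:
    """Published mediation decomposition tables (pathway/direct/total rows)."""
    src = resources.files("medipipe.data") / "reference_decompositions.csv"
    with src.open() as fh:
        return pd.read_csv(fh)
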