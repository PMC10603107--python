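"""Tabular I/O for abundance studies, reference lists, marker panels and filter traces.

All identifiers (protein accessions or gene symbols) are treated as opaque
keys and normalized to upper case; no accession-to-symbol mapping is
attempted.  Label-free intensity tables distinguish a missing cell (protein
not detected in that run, stored as NaN) from a measured zero: both count as
"not detected" for presence/absence rules, but only the missing cell is
excluded from fold-change means.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("exoscreen")

VALID_GROUPS = ("FT", "HGSOC")
VALID_SOURCES = ("cell_line", "tissue")


def normalize_id(identifier: str) -> str:
    """Case-normalize a protein identifier.  Idempotent."""
    return str(identifier).strip().upper()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one LC-MS/MS run: lineage group, source and replicate."""

    sample_id: str
    group: str           # "FT" or "HGSOC"
    source: str          # "cell_line" or "tissue"
    line_or_patient: str  # cell line name, or tissue-set name for explants
    replicate_index: int

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValueError(
                f"sample {self.sample_id!r}: group must be one of {VALID_GROUPS}, "
                f"got {self.group!r}"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"sample {self.sample_id!r}: source must be one of {VALID_SOURCES}, "
                f"got {self.source!r}"
            )
        if self.replicate_index < 1:
            raise ValueError(
                f"sample {self.sample_id!r}: replicate_index must be >= 1"
            )


@dataclass
class AbundanceStudy:
    """A proteins x samples label-free intensity matrix with sample metadata.

    ``intensities`` is a DataFrame indexed by case-normalized protein id with
    one column per sample; missing detections are NaN, measured zeros are 0.0.
    """

    intensities: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [normalize_id(p) for p in self.intensities.index]
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()]
        if len(dupes):
            raise ValueError(f"duplicate protein identifier(s): {sorted(set(dupes))}")
        self.intensities = self.intensities.copy()
        self.intensities.index = pd.Index(ids, name="protein")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in metadata")
        missing = [c for c in self.intensities.columns if c not in set(sample_ids)]
        if missing:
            raise ValueError(f"sample(s) in matrix absent from metadata: {missing}")
        # order columns to match metadata; metadata rows without a matrix
        # column are an error too (the study must be fully described)
        absent = [s for s in sample_ids if s not in self.intensities.columns]
        if absent:
            raise ValueError(f"sample(s) in metadata absent from matrix: {absent}")
        self.intensities = self.intensities[sample_ids]
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("negative intensities are not allowed")

    @property
    def proteins(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "source": [s.source for s in self.samples],
                "line_or_patient": [s.line_or_patient for s in self.samples],
                "replicate_index": [s.replicate_index for s in self.samples],
            }
        )

    def units(self) -> dict[tuple[str, str, str], list[str]]:
        """Replicate units keyed by (group, source, line_or_patient)."""
        out: dict[tuple[str, str, str], list[str]] = {}
        for s in self.samples:
            out.setdefault((s.group, s.source, s.line_or_patient), []).append(
                s.sample_id
            )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceStudy):
            return NotImplemented
        if self.samples != other.samples:
            return False
        a, b = self.intensities, other.intensities
        if not a.index.equals(b.index) or not a.columns.equals(b.columns):
            return False
        return np.array_equal(a.to_numpy(), b.to_numpy(), equal_nan=True)


@dataclass(frozen=True)
class ReferenceList:
    """A named set of protein identifiers (e.g. predicted-transmembrane list)."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference list {self.name!r} is empty")
        normed = frozenset(normalize_id(m) for m in self.members)
        object.__setattr__(self, "members", normed)


@dataclass
class MarkerPanel:
    """Samples x markers fluorescence panel with class labels.

    ``intensities`` is indexed by sample_id with one column per marker;
    ``labels`` maps each sample to its class ("case"/"control" or a
    cancer-type string).  All intensities must be positive after optional
    background subtraction (flooring at ``floor``).
    """

    intensities: pd.DataFrame
    labels: pd.Series
    background: Optional[dict[str, float]] = None
    floor: float = 1e-6

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if not self.intensities.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.intensities.index)
            if self.labels.isna().any():
                missing = list(self.labels.index[self.labels.isna()])
                raise ValueError(f"samples without labels: {missing}")
        if self.background:
            adj = self.intensities.copy()
            for marker, bkg in self.background.items():
                if marker in adj.columns:
                    adj[marker] = (adj[marker] - bkg).clip(lower=self.floor)
            self.intensities = adj
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("panel intensities must be finite")
        if (vals <= 0).any():
            bad = np.argwhere(vals <= 0)[0]
            raise ValueError(
                "non-positive intensity for sample "
                f"{self.intensities.index[bad[0]]!r}, marker "
                f"{self.intensities.columns[bad[1]]!r}"
            )

    @property
    def markers(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def values_for(self, marker: str, label: str) -> np.ndarray:
        if marker not in self.intensities.columns:
            raise KeyError(f"marker {marker!r} not in panel")
        mask = (self.labels == label).to_numpy()
        return self.intensities[marker].to_numpy(dtype=float)[mask]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        return (
            self.intensities.equals(other.intensities)
            and self.labels.equals(other.labels)
        )


# ---------------------------------------------------------------------------
# Delimited-text readers/writers
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path, override: Optional[str] = None) -> str:
    if override is not None:
        return override
    with open(path, newline="") as fh:
        head = fh.readline()
    try:
        return csv.Sniffer().sniff(head, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in head else ","


def read_abundance(
    path: str | Path,
    meta_path: str | Path,
    delimiter: Optional[str] = None,
) -> AbundanceStudy:
    """Read an intensity matrix (proteins x samples) and its sample metadata.

    Empty cells are read as missing (NaN); explicit zeros stay 0.0.
    Duplicate protein rows or samples missing from the metadata raise
    ``ValueError`` naming the offender.
    """
    path, meta_path = Path(path), Path(meta_path)
    delim = _sniff_delimiter(path, delimiter)
    mat = pd.read_csv(path, sep=delim, index_col=0, float_precision="round_trip")
    mat.index = [normalize_id(i) for i in mat.index]
    dup = pd.Index(mat.index)[pd.Index(mat.index).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate protein identifier(s): {sorted(set(dup))}")
    meta_delim = _sniff_delimiter(meta_path, delimiter)
    meta = pd.read_csv(meta_path, sep=meta_delim, dtype=str)
    required = {"sample_id", "group", "source", "line_or_patient", "replicate_index"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"metadata must have columns {sorted(required)}; got {list(meta.columns)}"
        )
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            group=row.group,
            source=row.source,
            line_or_patient=row.line_or_patient,
            replicate_index=int(row.replicate_index),
        )
        for row in meta.itertuples()
    ]
    return AbundanceStudy(intensities=mat.astype(float), samples=samples)


def write_abundance(
    study: AbundanceStudy,
    path: str | Path,
    meta_path: str | Path,
    delimiter: str = "\t",
) -> None:
    # %.17g round-trips doubles exactly
    study.intensities.to_csv(path, sep=delimiter, float_format="%.17g")
    study.meta_frame().to_csv(meta_path, sep=delimiter, index=False)


def read_reference_list(path: str | Path, name: str) -> ReferenceList:
    """Read a plain-text identifier list ('#' comments allowed), de-duplicated."""
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                members.append(normalize_id(line))
    if not members:
        raise ValueError(f"reference list file {path} is empty after parsing")
    unique = set(members)
    n_dup = len(members) - len(unique)
    if n_dup:
        logger.info("reference list %s: %d duplicate id(s) collapsed", name, n_dup)
    return ReferenceList(name=name, members=frozenset(unique), provenance=str(path))


def write_reference_list(ref: ReferenceList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {ref.name}\n")
        for m in sorted(ref.members):
            fh.write(m + "\n")


def read_panel(
    path: str | Path,
    labels_path: str | Path,
    delimiter: Optional[str] = None,
    background: Optional[dict[str, float]] = None,
) -> MarkerPanel:
    """Read a samples x markers intensity table and a sample_id,label table."""
    path, labels_path = Path(path), Path(labels_path)
    mat = pd.read_csv(
        path, sep=_sniff_delimiter(path, delimiter), index_col=0,
        float_precision="round_trip",
    )
    lab = pd.read_csv(
        labels_path, sep=_sniff_delimiter(labels_path, delimiter), dtype=str
    )
    if not {"sample_id", "label"}.issubset(lab.columns):
        raise ValueError("labels table must have columns sample_id,label")
    labels = lab.set_index("sample_id")["label"]
    return MarkerPanel(
        intensities=mat.astype(float), labels=labels, background=background
    )


def write_panel(
    panel: MarkerPanel,
    path: str | Path,
    labels_path: str | Path,
    delimiter: str = "\t",
) -> None:
    panel.intensities.to_csv(path, sep=delimiter, float_format="%.17g")
    pd.DataFrame(
        {"sample_id": panel.labels.index, "label": panel.labels.values}
    ).to_csv(labels_path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Filter trace serialization
# ---------------------------------------------------------------------------

def write_filter_trace(trace, path: str | Path, summary_path: str | Path | None = None) -> None:
    """Write a filter trace as JSON lines plus a TSV summary.

    One JSON record per stage: name, parameters, input/output counts and the
    sorted dropped identifiers.  The summary TSV holds the stage counts.
    """
    if not trace.stages:
        raise ValueError("cannot write an empty filter trace")
    path = Path(path)
    with open(path, "w") as fh:
        for st in trace.stages:
            rec = {
                "stage": st.name,
                "params": st.params,
                "n_in": len(st.set_in),
                "n_out": len(st.set_out),
                "dropped": sorted(st.set_in - st.set_out),
            }
            fh.write(json.dumps(rec) + "\n")
        if trace.final_ranked is not None:
            fh.write(
                json.dumps(
                    {
                        "stage": "__final_ranked__",
                        "ranked": [[p, fc] for p, fc in trace.final_ranked],
                    }
                )
                + "\n"
            )
    summary = Path(summary_path) if summary_path else path.with_suffix(path.suffix + ".summary.tsv")
    with open(summary, "w") as fh:
        fh.write("stage\tn_in\tn_out\tn_dropped\n")
        for st in trace.stages:
            fh.write(
                f"{st.name}\t{len(st.set_in)}\t{len(st.set_out)}\t"
                f"{len(st.set_in) - len(st.set_out)}\n"
            )


def read_filter_trace(path: str | Path) -> list[dict]:
    """Read back the JSON-lines trace records (stage name, counts, dropped)."""
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(json.loads(line))
    return records
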