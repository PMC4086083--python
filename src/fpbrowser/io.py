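"""Shared readers and writers.

All outputs are UTF-8 tab-separated text with a header row; ``#`` lines are
treated as comments on input. Formats: ``.smi`` libraries (``SMILES id
[vendor_mask]``), hits TSV (smiles, id, cbd), clusters TSV (smiles, id,
cbd, cluster), fingerprint dumps (id, space, total_sum, values) and
benchmark reports.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable

from .benchmark import EnrichmentReport
from .fingerprints import FingerprintVector, Space, fingerprint
from .index import SearchResult
from .standardize import MoleculeRecord, annotate


def write_smi(records: Iterable[MoleculeRecord], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for record in records:
            fh.write(f"{record.smiles} {record.id} {record.vendor_mask}\n")
    return path


def write_hits(result: SearchResult, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("smiles\tid\tcbd\n")
        for record, dist in result.hits:
            fh.write(f"{record.smiles}\t{record.id}\t{dist}\n")
    return path


def _data_rows(path: Path, expected_header: str) -> Iterable[list[str]]:
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if header != expected_header:
            raise ValueError(f"unexpected header in {path}: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def read_hits(
    path: str | Path, records_by_id: dict[str, MoleculeRecord] | None = None
) -> SearchResult:
    """Re-read a hits TSV into a :class:`SearchResult`.

    Molecules are looked up in ``records_by_id`` when given (preserving
    vendor masks), otherwise re-annotated from the stored SMILES.
    """
    path = Path(path)
    hits: list[tuple[MoleculeRecord, int]] = []
    for smiles, mol_id, dist in _data_rows(path, "smiles\tid\tcbd"):
        if records_by_id is not None and mol_id in records_by_id:
            record = records_by_id[mol_id]
        else:
            record = annotate(smiles, mol_id)
        hits.append((record, int(dist)))
    return SearchResult(hits=hits, histogram=dict(Counter(d for _, d in hits)))


def read_clusters(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Rows of a clusters TSV: (smiles, id, cbd, cluster), file order."""
    return [
        (smiles, mol_id, int(dist), int(label))
        for smiles, mol_id, dist, label in _data_rows(
            Path(path), "smiles\tid\tcbd\tcluster"
        )
    ]


def write_fingerprints(
    records: Iterable[MoleculeRecord], space: Space | str, path: str | Path
) -> Path:
    """Dump one fingerprint per record: id, space, total_sum, values."""
    space = Space(space)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tspace\ttotal_sum\tvalues\n")
        for record in records:
            fp = fingerprint(record, space)
            if space.is_binary:
                values = "".join("1" if v else "0" for v in fp.values)
            else:
                values = ",".join(str(v) for v in fp.values)
            fh.write(f"{record.id}\t{space.value}\t{fp.total_sum}\t{values}\n")
    return path


def write_benchmark_report(
    reports: Iterable[EnrichmentReport], path: str | Path
) -> Path:
    path = Path(path)
    reports = list(reports)
    fractions = sorted({f for report in reports for f in report.ef})
    ef_cols = [f"ef@{f:g}" for f in fractions]
    with path.open("w") as fh:
        fh.write("\t".join(["space", "scorer", "auc", *ef_cols]) + "\n")
        for report in reports:
            ef_values = [f"{report.ef[f]:.4f}" if f in report.ef else "" for f in fractions]
            fh.write(
                "\t".join(
                    [report.space.value, report.scorer, f"{report.auc:.4f}", *ef_values]
                )
                + "\n"
            )
    return path


def write_roc(report: EnrichmentReport, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
    return path
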