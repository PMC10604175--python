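"""Readers, writers and the labeled expression-matrix container.

The on-disk contract is deliberately plain: delimited text (TSV by
default, CSV recognised by extension) with samples in rows, a header row
of gene identifiers, and either an in-file label column or a separate
two-column ``sample_id<TAB>class`` file.  Everything the tool writes can
be re-read by the tool.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledExpression",
    "read_expression",
    "write_expression",
    "write_run_report",
]


@dataclass
class LabeledExpression:
    """A samples x genes real matrix with identifiers and two-class labels.

    ``labels`` may be any two distinct strings; ``y`` exposes the 0/1
    encoding, with the lexicographically first class name mapped to 0 so
    the encoding is deterministic regardless of file order.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: list[str]
    zero_variance_flags: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError(
                f"row count {n} must match sample_ids ({len(self.sample_ids)}) "
                f"and labels ({len(self.labels)})"
            )
        if len(self.gene_ids) != d:
            raise ValueError(f"column count {d} must match gene_ids ({len(self.gene_ids)})")
        dupes = pd.Index(self.gene_ids)[pd.Index(self.gene_ids).duplicated()].unique()
        if len(dupes):
            raise ValueError(f"duplicate gene identifiers: {', '.join(map(str, dupes))}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: sorted-first class -> 0, the other -> 1."""
        classes = self.classes
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, found {classes}")
        return np.array([0 if lab == classes[0] else 1 for lab in self.labels], dtype=int)

    def subset_genes(self, indices: np.ndarray | list[int]) -> "LabeledExpression":
        """A new container restricted to the given gene columns (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return LabeledExpression(
            values=self.values[:, idx],
            sample_ids=list(self.sample_ids),
            gene_ids=[self.gene_ids[i] for i in idx],
            labels=list(self.labels),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)
        df.insert(0, "class", self.labels)
        return df


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    data_path: str | Path,
    labels_path: str | Path | None = None,
    genes_in_rows: bool = False,
    label_column: str = "class",
) -> LabeledExpression:
    """Read a delimited expression matrix plus labels.

    Labels come from ``label_column`` inside the data file, or from a
    separate two-column file mapping sample id to class.  With
    ``genes_in_rows`` the matrix is transposed on read (header row then
    holds sample ids).
    """
    data_path = Path(data_path)
    sep = _sep_for(data_path)
    with open(data_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes and not genes_in_rows:
        raise ValueError(f"duplicate gene identifiers: {', '.join(dupes)}")
    df = pd.read_csv(data_path, sep=sep, index_col=0)
    labels: list[str] | None = None
    if not genes_in_rows and label_column in df.columns:
        labels = df[label_column].astype(str).tolist()
        df = df.drop(columns=[label_column])
    if genes_in_rows:
        df = df.T

    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at sample '{df.index[r]}', gene '{df.columns[c]}': "
            f"{df.iat[r, c]!r}"
        )
    values = df.to_numpy(dtype=float)
    sample_ids = df.index.astype(str).tolist()

    if labels_path is not None:
        lab_path = Path(labels_path)
        lab_df = pd.read_csv(lab_path, sep=_sep_for(lab_path), header=None, comment="#")
        if lab_df.shape[1] < 2:
            raise ValueError("label file must have two columns: sample id, class")
        mapping = dict(zip(lab_df.iloc[:, 0].astype(str), lab_df.iloc[:, 1].astype(str)))
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"label missing for sample(s): {', '.join(missing[:5])}")
        labels = [mapping[s] for s in sample_ids]
    if labels is None:
        raise ValueError(
            f"no labels: provide a '{label_column}' column or a separate label file"
        )
    return LabeledExpression(values, sample_ids, df.columns.astype(str).tolist(), labels)


def write_expression(data: LabeledExpression, data_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Write the matrix (samples in rows, label column included) and
    optionally a separate two-column label file."""
    data_path = Path(data_path)
    data.to_frame().to_csv(data_path, sep=_sep_for(data_path), index_label="sample_id")
    if labels_path is not None:
        labels_path = Path(labels_path)
        pd.DataFrame({"sample_id": data.sample_ids, "class": data.labels}).to_csv(
            labels_path, sep=_sep_for(labels_path), index=False, header=False
        )


def write_run_report(record, outdir: str | Path, gene_ids: list[str] | None = None) -> dict:
    """Emit the three run artifacts: selected-genes TSV, trace CSV, manifest.

    ``record`` is a :class:`sandcatfs.optimizer.RunRecord`.  Returns the
    paths written.  The trace CSV has exactly ``T + 1`` data rows: the
    initial all-ones state plus one row per iteration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = gene_ids if gene_ids is not None else record.gene_ids
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(len(record.best_bits))]

    sel_path = outdir / "selected_genes.tsv"
    sel_idx = np.flatnonzero(record.best_bits)
    pd.DataFrame(
        {"gene_id": [gene_ids[j] for j in sel_idx], "position": sel_idx}
    ).to_csv(sel_path, sep="\t", index=False)

    trace_path = outdir / "trace.csv"
    rows = []
    for t, fr in enumerate(record.trace):
        rows.append(
            {
                "iteration": t,
                "best_kappa": f"{fr.kappa:.10f}",
                "best_accuracy": f"{fr.accuracy:.10f}",
                "n_selected": fr.n_selected,
            }
        )
    pd.DataFrame(rows).to_csv(trace_path, index=False)

    import numpy as np_mod
    import sklearn

    from . import __version__

    manifest_path = outdir / "run_manifest.json"
    manifest = {
        "versions": {
            "sandcatfs": __version__,
            "numpy": np_mod.__version__,
            "sklearn": sklearn.__version__,
        },
        "algorithm": record.algorithm,
        "seed": record.seed,
        "config": record.config,
        "evaluations": record.evaluations,
        "fitness_queries": record.fitness_queries,
        "best_kappa": record.best_fitness.kappa,
        "best_accuracy": record.best_fitness.accuracy,
        "n_selected": int(record.best_fitness.n_selected),
        "n_genes": len(record.best_bits),
        "label_encoding": record.config.get("label_encoding"),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"selected": sel_path, "trace": trace_path, "manifest": manifest_path}


def read_selected_genes(path: str | Path, n_genes: int) -> np.ndarray:
    """Rebuild a bit-vector from a selected-genes table."""
    df = pd.read_csv(path, sep="\t")
    bits = np.zeros(n_genes, dtype=np.int8)
    bits[df["position"].to_numpy(dtype=int)] = 1
    return bits
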