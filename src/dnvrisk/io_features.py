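"""Variant and gene-score input handling and feature-matrix construction.

Two variant-class-specific matrix flavours are produced:

* LGD mode — binary gene indicators, optionally followed by four per-sample
  gene-score features (pLI, LOEUF, RVIS, phastCons) aggregated over the
  sample's mutated genes by the most-deleterious value.
* missense mode — gene cells hold the maximum per-variant pathogenicity
  score among the sample's missense variants in that gene; no gene-score
  columns are appended.

A ``trivial`` mode restricts either flavour to presence/absence indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaAlignmentError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical gene-score feature names, in matrix column order.
SCORE_NAMES: tuple[str, ...] = ("pli", "loeuf", "rvis", "phastcons")

#: Least-constrained fill-in values for genes missing a score.
SCORE_IMPUTE: dict[str, float] = {
    "pli": 0.0,
    "loeuf": 2.0,
    "rvis": 0.0,
    "phastcons": 0.0,
}

# Direction of "most deleterious" per score: max for pLI/phastCons
# (high = constrained/conserved), min for LOEUF/RVIS (low = intolerant).
_AGG_MAX = {"pli": True, "loeuf": False, "rvis": False, "phastcons": True}

#: Neutral pathogenicity assigned to missense variants lacking a score.
DEFAULT_PATHOGENICITY = 0.5

REQUIRED_VARIANT_COLUMNS = ("SampleID", "Phenotype", "Gene", "Class")
PATHOGENICITY_COLUMN = "PrimateAI"


class Phenotype(str, Enum):
    CASE = "case"
    CONTROL = "control"


class VariantClass(str, Enum):
    LGD = "lgd"
    MISSENSE = "missense"
    OTHER = "other"


@dataclass(frozen=True)
class VariantRecord:
    """A single de novo coding variant observed in one individual."""

    sample_id: str
    phenotype: Phenotype
    gene: str
    variant_class: VariantClass
    pathogenicity: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene symbol must be non-empty")
        if self.pathogenicity is not None:
            if self.variant_class is not VariantClass.MISSENSE:
                raise ValidationError(
                    "pathogenicity is defined for missense variants only"
                )
            if not 0.0 <= self.pathogenicity <= 1.0:
                raise ValidationError(
                    f"pathogenicity {self.pathogenicity} outside [0, 1]"
                )


def read_variants(
    path: str | Path,
    class_filter: Iterable[VariantClass] | None = None,
) -> list[VariantRecord]:
    """Read a tab-separated variant table into :class:`VariantRecord` rows.

    Parameters
    ----------
    path
        TSV with header columns ``SampleID``, ``Phenotype``, ``Gene``,
        ``Class`` and optionally ``PrimateAI`` (float or ``NA``).
    class_filter
        Variant classes to keep; ``None`` keeps everything. Records are
        returned in file order.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file, expected a header row") from exc
    for column in REQUIRED_VARIANT_COLUMNS:
        if column not in frame.columns:
            raise FormatError(f"{path}: missing required column '{column}'")

    keep = set(class_filter) if class_filter is not None else None
    has_score = PATHOGENICITY_COLUMN in frame.columns
    records: list[VariantRecord] = []
    for position, row in enumerate(frame.itertuples(index=False)):
        line_number = position + 2  # header is line 1
        data = row._asdict()
        try:
            phenotype = Phenotype(str(data["Phenotype"]).strip().lower())
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{line_number}: unknown phenotype {data['Phenotype']!r}"
            ) from exc
        try:
            variant_class = VariantClass(str(data["Class"]).strip().lower())
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{line_number}: unknown variant class {data['Class']!r}"
            ) from exc

        pathogenicity: float | None = None
        if has_score:
            raw = data[PATHOGENICITY_COLUMN]
            if raw is not None and not pd.isna(raw) and str(raw).strip().upper() not in ("", "NA", "NAN"):
                try:
                    pathogenicity = float(raw)
                except ValueError as exc:
                    raise ValidationError(
                        f"{path}:{line_number}: non-numeric {PATHOGENICITY_COLUMN} "
                        f"value {raw!r}"
                    ) from exc
                if not 0.0 <= pathogenicity <= 1.0:
                    raise ValidationError(
                        f"{path}:{line_number}: {PATHOGENICITY_COLUMN} value "
                        f"{pathogenicity} outside [0, 1]"
                    )
        if pathogenicity is not None and variant_class is not VariantClass.MISSENSE:
            logger.debug(
                "%s:%d: ignoring pathogenicity on non-missense variant",
                path,
                line_number,
            )
            pathogenicity = None

        if keep is not None and variant_class not in keep:
            continue
        records.append(
            VariantRecord(
                sample_id=str(data["SampleID"]),
                phenotype=phenotype,
                gene=str(data["Gene"]).strip(),
                variant_class=variant_class,
                pathogenicity=pathogenicity,
            )
        )
    return records


@dataclass
class GeneScoreTable:
    """Per-gene constraint/conservation scores; NaN marks a missing score.

    The backing frame is indexed by gene symbol (bare string, case
    sensitive) with one column per entry of :data:`SCORE_NAMES`.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for name in SCORE_NAMES:
            if name not in self.table.columns:
                self.table[name] = np.nan
        self.table = self.table[list(SCORE_NAMES)].astype(float)
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene symbols in score table")
        bad_pli = self.table["pli"].dropna()
        if ((bad_pli < 0) | (bad_pli > 1)).any():
            raise ValidationError("pLI values must lie in [0, 1]")
        bad_pc = self.table["phastcons"].dropna()
        if ((bad_pc < 0) | (bad_pc > 1)).any():
            raise ValidationError("phastCons values must lie in [0, 1]")

    @classmethod
    def from_dict(cls, scores: Mapping[str, Mapping[str, float]]) -> "GeneScoreTable":
        frame = pd.DataFrame.from_dict(scores, orient="index")
        frame.index.name = "Gene"
        return cls(frame)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def is_missing(self, gene: str, score: str) -> bool:
        if gene not in self.table.index:
            return True
        return bool(pd.isna(self.table.at[gene, score]))

    def features_for(self, gene: str) -> np.ndarray:
        """Imputed score vector for one gene, ordered as SCORE_NAMES."""
        out = np.empty(len(SCORE_NAMES))
        for j, name in enumerate(SCORE_NAMES):
            if self.is_missing(gene, name):
                logger.info("imputing %s for gene %s -> %s", name, gene, SCORE_IMPUTE[name])
                out[j] = SCORE_IMPUTE[name]
            else:
                out[j] = float(self.table.at[gene, name])
        return out


def read_gene_scores(paths: Mapping[str, str | Path]) -> GeneScoreTable:
    """Join per-score two-column TSVs (``Gene<TAB>Score``) on gene symbol.

    ``paths`` maps score names (subset of :data:`SCORE_NAMES`) to files.
    Genes absent from a file are flagged missing (NaN) for that score.
    """
    unknown = set(paths) - set(SCORE_NAMES)
    if unknown:
        raise ValueError(f"unknown score names: {sorted(unknown)}")
    columns: dict[str, pd.Series] = {}
    for name, path in paths.items():
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        if frame.shape[1] < 2:
            raise FormatError(f"{path}: expected two columns (Gene, score)")
        genes = frame.iloc[:, 0].astype(str)
        values = []
        for gene, raw in zip(genes, frame.iloc[:, 1]):
            try:
                values.append(float(raw))
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: non-numeric {name} score for gene '{gene}'"
                ) from exc
        columns[name] = pd.Series(values, index=genes, name=name)
    joined = pd.DataFrame(columns)
    joined.index.name = "Gene"
    return GeneScoreTable(joined)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a heuristic gene list: one symbol per line, ``#`` comments."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            symbols.add(token)
    return symbols


@dataclass
class FeatureMatrix:
    """Samples x (gene indicators + optional gene-score features) matrix."""

    sample_ids: list[str]
    gene_columns: list[str]
    score_columns: list[str]
    values: np.ndarray
    labels: np.ndarray
    variant_class: VariantClass

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n_features = len(self.gene_columns) + len(self.score_columns)
        if self.values.shape != (len(self.sample_ids), n_features):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {n_features} features"
            )
        if self.labels.shape != (len(self.sample_ids),):
            raise ValidationError("labels length must equal sample count")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 (control) or 1 (case)")

    @property
    def feature_names(self) -> list[str]:
        return self.gene_columns + self.score_columns

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def gene_part(self) -> np.ndarray:
        return self.values[:, : len(self.gene_columns)]

    def subset(self, sample_ids: Iterable[str]) -> "FeatureMatrix":
        """Row subset in the given order; unknown ids raise KeyError."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            gene_columns=list(self.gene_columns),
            score_columns=list(self.score_columns),
            values=self.values[rows].copy(),
            labels=self.labels[rows].copy(),
            variant_class=self.variant_class,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write ``SampleID, <genes...>, <scores...>, Label`` (round-trips)."""
        with open(path, "w") as handle:
            header = ["SampleID", *self.feature_names, "Label"]
            handle.write("\t".join(header) + "\n")
            for i, sample in enumerate(self.sample_ids):
                cells = [sample]
                cells.extend(repr(float(v)) for v in self.values[i])
                cells.append(str(int(self.labels[i])))
                handle.write("\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, variant_class: VariantClass) -> "FeatureMatrix":
        frame = pd.read_csv(
            path, sep="\t", dtype={"SampleID": str}, float_precision="round_trip"
        )
        if "SampleID" not in frame.columns or "Label" not in frame.columns:
            raise FormatError(f"{path}: expected SampleID and Label columns")
        feature_names = [c for c in frame.columns if c not in ("SampleID", "Label")]
        score_columns = [c for c in feature_names if c in SCORE_NAMES]
        gene_columns = [c for c in feature_names if c not in SCORE_NAMES]
        return cls(
            sample_ids=list(frame["SampleID"]),
            gene_columns=gene_columns,
            score_columns=score_columns,
            values=frame[gene_columns + score_columns].to_numpy(dtype=float),
            labels=frame["Label"].to_numpy(dtype=int),
            variant_class=variant_class,
        )


def build_feature_matrix(
    variants: Sequence[VariantRecord],
    scores: GeneScoreTable,
    variant_class: VariantClass,
    mode: str = "full",
) -> FeatureMatrix:
    """Construct a variant-class-specific feature matrix.

    Samples with no variant of ``variant_class`` are excluded (the models
    are class-specific). ``mode`` is ``"full"`` or ``"trivial"``; trivial
    restricts the matrix to 0/1 presence indicators for either class.
    """
    if mode not in ("full", "trivial"):
        raise ValueError(f"unknown mode {mode!r}")
    if variant_class not in (VariantClass.LGD, VariantClass.MISSENSE):
        raise ValueError("feature matrices are built for LGD or missense only")
    subset = [v for v in variants if v.variant_class is variant_class]
    if not subset:
        raise ValidationError(
            f"no variants of class '{variant_class.value}' to build a matrix from"
        )

    if variant_class is VariantClass.MISSENSE and mode == "full":
        if all(v.pathogenicity is None for v in subset):
            raise ValidationError(
                "all missense variants lack pathogenicity scores; supply "
                "PrimateAI values or accept the neutral 0.5 fill by setting "
                "scores explicitly, or build in trivial mode"
            )

    sample_ids: list[str] = []
    label_of: dict[str, int] = {}
    for v in subset:
        value = 1 if v.phenotype is Phenotype.CASE else 0
        if v.sample_id not in label_of:
            sample_ids.append(v.sample_id)
            label_of[v.sample_id] = value
        elif label_of[v.sample_id] != value:
            raise ValidationError(
                f"sample '{v.sample_id}' appears with conflicting phenotypes"
            )
    gene_columns = sorted({v.gene for v in subset})
    gene_index = {g: j for j, g in enumerate(gene_columns)}
    sample_index = {s: i for i, s in enumerate(sample_ids)}

    n, g = len(sample_ids), len(gene_columns)
    indicators = np.zeros((n, g))
    for v in subset:
        i, j = sample_index[v.sample_id], gene_index[v.gene]
        if variant_class is VariantClass.MISSENSE and mode == "full":
            score = v.pathogenicity
            if score is None:
                logger.warning(
                    "missense variant in %s/%s lacks a pathogenicity score; "
                    "filling with %.1f",
                    v.sample_id,
                    v.gene,
                    DEFAULT_PATHOGENICITY,
                )
                score = DEFAULT_PATHOGENICITY
            indicators[i, j] = max(indicators[i, j], score)
        else:
            indicators[i, j] = 1.0

    score_columns: list[str] = []
    values = indicators
    if variant_class is VariantClass.LGD and mode == "full":
        score_columns = list(SCORE_NAMES)
        per_gene = np.vstack([scores.features_for(g) for g in gene_columns])
        sample_scores = np.zeros((n, len(SCORE_NAMES)))
        for i in range(n):
            mutated = np.flatnonzero(indicators[i] > 0)
            block = per_gene[mutated]
            for j, name in enumerate(SCORE_NAMES):
                agg = np.max if _AGG_MAX[name] else np.min
                sample_scores[i, j] = agg(block[:, j])
        values = np.hstack([indicators, sample_scores])

    labels = np.array([label_of[s] for s in sample_ids], dtype=int)
    return FeatureMatrix(
        sample_ids=sample_ids,
        gene_columns=gene_columns,
        score_columns=score_columns,
        values=values,
        labels=labels,
        variant_class=variant_class,
    )


def align_features(matrix: FeatureMatrix, schema: Sequence[str]) -> np.ndarray:
    """Reorder/zero-fill matrix columns to a trained model's schema.

    Columns absent from the schema are dropped (and logged); schema columns
    absent from the matrix contribute zeros. Raises
    :class:`SchemaAlignmentError` when the two share no columns.
    """
    schema = list(schema)
    have = {name: j for j, name in enumerate(matrix.feature_names)}
    shared = [name for name in schema if name in have]
    if not shared:
        raise SchemaAlignmentError(
            "no feature columns shared between data and model schema"
        )
    dropped = [name for name in matrix.feature_names if name not in set(schema)]
    if dropped:
        logger.info(
            "dropping %d feature columns unseen by the model (e.g. %s)",
            len(dropped),
            dropped[:5],
        )
    out = np.zeros((matrix.n_samples, len(schema)))
    for j, name in enumerate(schema):
        if name in have:
            out[:, j] = matrix.values[:, have[name]]
    return out
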