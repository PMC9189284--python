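"""Synthetic labelled expression matrices with known marker structure.

The generator emulates the statistical shape of a multi-class single-cell
TPM matrix: ``C`` cell types with unequal class sizes, ``G`` genes of which a
small disjoint subset per class are up-shifted markers, heavy-tailed
non-negative noise (log-normal), and multiplicative dropout (each entry is
zeroed independently with a fixed probability, mimicking the sparsity of
single-cell counts).  Entry for gene ``g`` in a cell of class ``c`` is

    exp( Normal(baseline_log_mean + effect_size * [g is a marker of c],
                baseline_log_sd) )

then zeroed with probability ``dropout_rate``.  Marker assignment is
deterministic: the first ``markers_per_class * n_classes`` gene indices,
partitioned in class order, so recovery tests are self-describing.

:func:`table1_sizes` provides a realistic fixture configuration: the 16
hepatic cell-type sample sizes (1,147 cells in total) of an in-vitro
hepatocyte differentiation study, spanning a 12-fold class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import LabelledMatrix
from .errors import ConfigurationError

__all__ = [
    "SyntheticConfig",
    "MarkerMap",
    "generate",
    "table1_sizes",
    "TABLE1_CELL_TYPES",
    "default_fixture_config",
]

#: the 16 hepatic cell types of the reference dataset, in table order
TABLE1_CELL_TYPES: tuple[str, ...] = (
    "5C-condition cultured human primary hepatocyte",
    "Cultured human primary intrahepatic biliary epithelial cell",
    "Definitive endoderm",
    "Endoderm stem cell (EnSC)",
    "EnSC-derived cholangiocyte",
    "EnSC-derived EGFi-untreated hepatocyte",
    "EnSC-derived hepatic endoderm",
    "EnSC-derived hepatoblast",
    "EnSC-derived hepatocyte",
    "EnSC-derived immature hepatocyte",
    "EnSC-derived TPPB-untreated cholangiocyte",
    "Hepatocyte derived from ProliHH P2 through 3D maturation",
    "Hepatocyte derived from ProliHH P5 through 3D maturation",
    "Human embryonic stem cell-derived hepatocyte-like cell",
    "Sorted ALB+ CYP3A4+ EnSC-derived hepatocyte",
    "Uncultured adult human primary hepatocyte",
)

_TABLE1_SIZES: tuple[int, ...] = (96, 34, 15, 24, 68, 128, 59, 84, 177, 31, 75, 22, 32, 140, 67, 95)


def table1_sizes() -> list[int]:
    """The 16 published per-cell-type sample sizes (sum 1,147; max/min 177/15).

    Class labels for the same table order are in :data:`TABLE1_CELL_TYPES`.
    """
    return list(_TABLE1_SIZES)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the log-normal marker-signal generator.

    ``effect_size`` is the log-scale mean shift a marker gene receives in its
    own class; ``dropout_rate`` is the probability any entry is zeroed.
    """

    n_classes: int
    class_sizes: tuple[int, ...]
    n_genes: int
    markers_per_class: int = 5
    effect_size: float = 2.5
    baseline_log_mean: float = 1.0
    baseline_log_sd: float = 1.0
    dropout_rate: float = 0.3
    seed: int = 0
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        object.__setattr__(self, "class_sizes", tuple(int(s) for s in self.class_sizes))
        if self.class_labels is not None:
            object.__setattr__(self, "class_labels", tuple(self.class_labels))

    def validate(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be a positive integer")
        if len(self.class_sizes) != self.n_classes:
            raise ConfigurationError(
                f"class_sizes has length {len(self.class_sizes)}, expected n_classes={self.n_classes}"
            )
        if any(s < 2 for s in self.class_sizes):
            raise ConfigurationError("every class_sizes entry must be >= 2 (SMOTE and stratified CV need >=2 per class)")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        if self.markers_per_class < 0:
            raise ConfigurationError("markers_per_class must be non-negative")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ConfigurationError(
                "markers_per_class * n_classes exceeds n_genes (marker sets must be disjoint)"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.baseline_log_sd <= 0:
            raise ConfigurationError("baseline_log_sd must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1]")
        if self.class_labels is not None and len(self.class_labels) != self.n_classes:
            raise ConfigurationError("class_labels length must equal n_classes")

    def labels(self) -> list[str]:
        if self.class_labels is not None:
            return list(self.class_labels)
        width = len(str(self.n_classes))
        return [f"class_{i + 1:0{width}d}" for i in range(self.n_classes)]


#: mapping class label -> set of gene ids designated as that class's markers
MarkerMap = dict


def generate(config: SyntheticConfig) -> tuple[LabelledMatrix, MarkerMap]:
    """Draw one labelled matrix and its ground-truth marker map.

    Returns a ``sum(class_sizes)`` x ``n_genes`` :class:`LabelledMatrix` and a
    mapping class label -> set of marker gene ids (pairwise disjoint).
    Identical configs (including seed) give bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels_by_class = config.labels()
    n_cells = sum(config.class_sizes)
    gene_ids = [f"g{j + 1:05d}" for j in range(config.n_genes)]
    cell_ids = [f"cell{j + 1:05d}" for j in range(n_cells)]

    cell_class = np.repeat(np.arange(config.n_classes), config.class_sizes)
    labels = [labels_by_class[k] for k in cell_class]

    # disjoint marker blocks: class k owns gene columns [k*m, (k+1)*m)
    m = config.markers_per_class
    shift = np.zeros((config.n_classes, config.n_genes))
    marker_map: MarkerMap = {}
    for k, lab in enumerate(labels_by_class):
        cols = range(k * m, (k + 1) * m)
        marker_map[lab] = {gene_ids[j] for j in cols}
        shift[k, list(cols)] = config.effect_size

    log_expr = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=(n_cells, config.n_genes))
    log_expr += shift[cell_class]
    values = np.exp(log_expr)
    if config.dropout_rate > 0:
        values[rng.random(values.shape) < config.dropout_rate] = 0.0

    return LabelledMatrix(values, cell_ids, gene_ids, labels), marker_map


def default_fixture_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The desk-scale study fixture: 16 classes with the published sizes,
    500 genes, 5 markers per class at effect 2.5, 30% dropout."""
    cfg = SyntheticConfig(
        n_classes=16,
        class_sizes=tuple(table1_sizes()),
        n_genes=500,
        markers_per_class=5,
        effect_size=2.5,
        baseline_log_mean=1.0,
        baseline_log_sd=1.0,
        dropout_rate=0.3,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
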