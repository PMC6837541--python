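"""Synthetic mixed-population expression matrices with planted markers.

The generator emulates the structure the selection method assumes: a mix of
cell populations in which marker genes are "on" (shifted log-scale mean) in
one population and "off" elsewhere, hence bimodal across the mixture, while
background genes are unimodal everywhere. Markers assigned to the same
population co-occur; markers of different populations are mutually
exclusive — so both graph kinds are exercised. Dropout is modelled as
independent zeroing of entries, reproducing the zero inflation of real
single-cell data.

Values are drawn directly on the log scale (Gaussian components, clipped at
zero) rather than as negative-binomial counts: the selector operates on log
expression densities, and the Gaussian mixture keeps the expected behaviour
of every pipeline stage analytically transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .evaluate import CellLabeling
from .io import ExpressionMatrix, write_dense, write_mtx


@dataclass
class SimulationConfig:
    """Reference conditions: 500 cells, 1000 genes, two equal populations,
    40 markers (20 per population), on/off separation 4 log2 units,
    component sd 0.5, 10% dropout.

    ``base_mean`` is kept low (1.0 log2 units) so that for background genes
    the dropout mass at zero merges with the baseline expression mode into a
    single density peak, as it does for ubiquitously low-expressed genes in
    real data; marker "on" cells sit ``marker_shift`` above it.
    """

    n_cells: int = 500
    n_genes: int = 1000
    n_populations: int = 2
    population_fractions: list[float] | None = None
    n_marker_genes: int = 40
    marker_shift: float = 4.0
    base_mean: float = 1.0
    base_sd: float = 0.5
    dropout_rate: float = 0.1
    seed: int = 0

    def resolved_fractions(self) -> np.ndarray:
        if self.population_fractions is None:
            return np.full(self.n_populations, 1.0 / self.n_populations)
        return np.asarray(self.population_fractions, dtype=float)

    def validate(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 cells and 1 gene")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations")
        if not 0 <= self.n_marker_genes <= self.n_genes:
            raise ValueError("n_marker_genes must be within [0, n_genes]")
        fractions = self.resolved_fractions()
        if fractions.size != self.n_populations:
            raise ValueError(
                f"{fractions.size} population fractions for {self.n_populations} populations"
            )
        if (fractions <= 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("population fractions must be positive and sum to 1")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be a probability")
        if self.base_sd <= 0 or self.marker_shift < 0:
            raise ValueError("base_sd must be > 0 and marker_shift >= 0")


def simulate(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, CellLabeling, list[str]]:
    """Draw one matrix; returns (log-scale matrix, true labels, true markers).

    Marker gene g is assigned an "on" population (round-robin over
    populations); its cells draw Normal(base_mean + marker_shift, base_sd)
    when in that population and Normal(base_mean, base_sd) otherwise, clipped
    at 0. Background genes draw the baseline for every cell. Each entry is
    then zeroed independently with probability ``dropout_rate``.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fractions = config.resolved_fractions()
    labels = rng.choice(config.n_populations, size=config.n_cells, p=fractions)

    values = rng.normal(
        config.base_mean, config.base_sd, size=(config.n_genes, config.n_cells)
    )
    # scatter markers over random gene rows; round-robin "on" population
    marker_rows = rng.choice(config.n_genes, size=config.n_marker_genes, replace=False)
    marker_rows.sort()
    for rank, row in enumerate(marker_rows):
        on_pop = rank % config.n_populations
        on_cells = labels == on_pop
        values[row, on_cells] += config.marker_shift
    values = np.clip(values, 0.0, None)
    if config.dropout_rate > 0:
        dropped = rng.random(values.shape) < config.dropout_rate
        values[dropped] = 0.0

    width = max(4, len(str(config.n_genes - 1)))
    gene_ids = [f"g{i:0{width}d}" for i in range(config.n_genes)]
    cell_ids = [f"cell{j:04d}" for j in range(config.n_cells)]
    matrix = ExpressionMatrix(
        values=values,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        scale="log",
        platform="smart_seq",
    )
    truth = CellLabeling(cell_ids=cell_ids, labels=labels)
    markers = [gene_ids[i] for i in marker_rows]
    return matrix, truth, markers


def write_fixture(config: SimulationConfig, directory: str | Path) -> None:
    """Write one simulated dataset in both supported layouts plus truth files.

    Produces ``matrix.tsv`` (dense), ``mtx/`` (matrix-market triplet),
    ``markers.txt`` and ``labels.tsv`` under ``directory``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix, truth, markers = simulate(config)
    write_dense(matrix, directory / "matrix.tsv")
    write_mtx(matrix, directory / "mtx")
    (directory / "markers.txt").write_text("".join(f"{g}\n" for g in markers))
    with open(directory / "labels.tsv", "w") as fh:
        fh.write("cell_id\tlabel\n")
        for cell, lab in zip(truth.cell_ids, truth.labels):
            fh.write(f"{cell}\t{lab}\n")
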