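"""Reading, validating and writing locus intensity tables and genotype calls.

A locus is observed as a long-form table with one two-channel intensity
observation per row: an individual identifier and the raw signal intensities
``x`` and ``y`` of the two alleles.  Replicate observations of the same
individual occupy multiple rows.  For F1 crosses, replicate observations of
the two parents may be supplied either through a role column
(``progeny``/``parent1``/``parent2``) or as separate files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

ROLE_PROGENY = "progeny"
ROLE_PARENT1 = "parent1"
ROLE_PARENT2 = "parent2"


class FormatError(ValueError):
    """The input table does not have the expected columns/structure."""


class ValidationError(ValueError):
    """A row violates the intensity-data invariants."""


@dataclass(frozen=True)
class SamplePoint:
    """One two-channel intensity observation tied to an individual.

    ``x`` and ``y`` are the signal intensities of the two alleles (arbitrary
    units, non-negative, not both zero).  Only the ratio ``x/(x+y)`` carries
    genotype information; the total intensity is nuisance scale.
    """

    individual_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValidationError(
                f"negative intensity for individual {self.individual_id!r}: "
                f"({self.x}, {self.y})"
            )
        if self.x + self.y == 0:
            raise ValidationError(
                f"zero total intensity for individual {self.individual_id!r}"
            )


@dataclass
class LocusDataset:
    """All intensity observations for one locus, grouped by individual.

    ``points`` preserves input row order.  Parental replicate blocks are both
    present or both absent.  ``measure`` records which intensity measure the
    columns carried (peak height vs peak area for mass-spec assays); the model
    itself is agnostic.
    """

    locus_id: str
    points: Sequence[SamplePoint]
    parent1_points: Sequence[SamplePoint] | None = None
    parent2_points: Sequence[SamplePoint] | None = None
    measure: str = "height"
    n_dropped_rows: int = 0

    def __post_init__(self) -> None:
        if (self.parent1_points is None) != (self.parent2_points is None):
            raise ValidationError(
                "parent1 and parent2 blocks must be both present or both absent"
            )
        if not self.points:
            raise ValidationError(f"locus {self.locus_id!r} has no observations")
        if self.measure not in ("height", "area"):
            raise ValidationError(f"unknown intensity measure {self.measure!r}")

    @property
    def has_parent_data(self) -> bool:
        return self.parent1_points is not None

    @property
    def individuals(self) -> list[str]:
        """Individual ids in order of first appearance."""
        seen: dict[str, None] = {}
        for pt in self.points:
            seen.setdefault(pt.individual_id, None)
        return list(seen)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def points_by_individual(self) -> dict[str, list[SamplePoint]]:
        grouped: dict[str, list[SamplePoint]] = {}
        for pt in self.points:
            grouped.setdefault(pt.individual_id, []).append(pt)
        return grouped

    def replicate_counts(self) -> dict[str, int]:
        return {ind: len(pts) for ind, pts in self.points_by_individual().items()}


def _points_from_frame(
    df: pd.DataFrame,
    id_col: str,
    x_col: str,
    y_col: str,
    zero_policy: str,
) -> tuple[list[SamplePoint], int]:
    points: list[SamplePoint] = []
    dropped = 0
    for row_idx, row in enumerate(df.itertuples(index=False)):
        ind = str(getattr(row, id_col))
        x = float(getattr(row, x_col))
        y = float(getattr(row, y_col))
        if x < 0 or y < 0:
            raise ValidationError(
                f"row {row_idx}: negative intensity ({x}, {y}) for {ind!r}"
            )
        if x + y == 0:
            if zero_policy == "drop":
                logger.warning(
                    "dropping zero-total-intensity row %d (individual %r)",
                    row_idx,
                    ind,
                )
                dropped += 1
                continue
            raise ValidationError(
                f"row {row_idx}: zero total intensity for individual {ind!r} "
                "(zero_policy='error')"
            )
        points.append(SamplePoint(ind, x, y))
    return points, dropped


def read_locus(
    path: str | Path,
    *,
    delimiter: str | None = None,
    id_col: str = "individual",
    x_col: str = "x",
    y_col: str = "y",
    role_col: str = "role",
    zero_policy: str = "error",
    locus_id: str | None = None,
    measure: str = "height",
    parent1_path: str | Path | None = None,
    parent2_path: str | Path | None = None,
) -> LocusDataset:
    """Read a long-form delimited intensity table into a :class:`LocusDataset`.

    Parameters
    ----------
    path
        Delimited text file with one observation per row.  The delimiter is
        sniffed when ``delimiter`` is None.
    zero_policy
        ``"error"`` (default) rejects rows with ``x + y == 0`` naming the row;
        ``"drop"`` removes them with a logged warning.  Zero-total rows are
        never silently kept.
    role_col
        Optional column marking rows as ``progeny``, ``parent1`` or
        ``parent2``.  Alternatively parental replicates may be supplied as
        two separate files via ``parent1_path``/``parent2_path``.
    """
    if zero_policy not in ("error", "drop"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if delimiter is None:
        # sniff from the header line; round-trip float parsing needs the
        # C engine, which cannot sniff by itself
        header = path.open(encoding="utf-8").readline()
        delimiter = "\t" if header.count("\t") >= header.count(",") else ","
    read_kwargs: dict = {"sep": delimiter, "float_precision": "round_trip"}
    df = pd.read_csv(path, **read_kwargs)

    missing = [c for c in (id_col, x_col, y_col) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    if role_col in df.columns and parent1_path is None:
        roles = df[role_col].astype(str)
        bad = set(roles) - {ROLE_PROGENY, ROLE_PARENT1, ROLE_PARENT2}
        if bad:
            raise FormatError(f"{path}: unknown role value(s) {sorted(bad)}")
        progeny_df = df[roles == ROLE_PROGENY]
        p1_df = df[roles == ROLE_PARENT1]
        p2_df = df[roles == ROLE_PARENT2]
    else:
        progeny_df, p1_df, p2_df = df, None, None

    points, dropped = _points_from_frame(progeny_df, id_col, x_col, y_col, zero_policy)

    parent1_points = parent2_points = None
    if parent1_path is not None or parent2_path is not None:
        if parent1_path is None or parent2_path is None:
            raise ValidationError("parent1_path and parent2_path must both be given")
        for ppath, label in ((parent1_path, ROLE_PARENT1), (parent2_path, ROLE_PARENT2)):
            pdf = pd.read_csv(Path(ppath), **read_kwargs)
            if any(c not in pdf.columns for c in (id_col, x_col, y_col)):
                raise FormatError(f"{ppath}: missing required columns")
            pts, pdrop = _points_from_frame(pdf, id_col, x_col, y_col, zero_policy)
            dropped += pdrop
            if label == ROLE_PARENT1:
                parent1_points = pts
            else:
                parent2_points = pts
    elif p1_df is not None and (len(p1_df) or len(p2_df)):
        if len(p1_df) == 0 or len(p2_df) == 0:
            raise ValidationError(
                f"{path}: parental blocks must be both present or both absent"
            )
        parent1_points, d1 = _points_from_frame(p1_df, id_col, x_col, y_col, zero_policy)
        parent2_points, d2 = _points_from_frame(p2_df, id_col, x_col, y_col, zero_policy)
        dropped += d1 + d2

    return LocusDataset(
        locus_id=locus_id or path.stem,
        points=points,
        parent1_points=parent1_points,
        parent2_points=parent2_points,
        measure=measure,
        n_dropped_rows=dropped,
    )


def write_locus(dataset: LocusDataset, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a dataset back to a long-form delimited table (role column included)."""
    rows = []
    for pt in dataset.points:
        rows.append((pt.individual_id, pt.x, pt.y, ROLE_PROGENY))
    for pts, role in (
        (dataset.parent1_points, ROLE_PARENT1),
        (dataset.parent2_points, ROLE_PARENT2),
    ):
        if pts:
            rows.extend((pt.individual_id, pt.x, pt.y, role) for pt in pts)
    df = pd.DataFrame(rows, columns=["individual", "x", "y", "role"])
    # default float formatting is the shortest round-trip repr: exact
    df.to_csv(path, sep=delimiter, index=False)


def write_calls(
    result,
    dataset: LocusDataset,
    path: str | Path,
    posterior_threshold: float = 0.0,
) -> None:
    """Write per-individual dosage calls as TSV.

    ``result`` is an :class:`~polydose.inference.FitResult`.  Each individual
    gets its called dosage, the posterior of that call, and an inclusion flag
    (posterior >= threshold); individuals below the threshold are still
    written but flagged excluded.  Header comment lines record the fitted
    ploidy, sigma, population parameters and configuration posterior.
    """
    if not 0.0 <= posterior_threshold <= 1.0:
        raise ValueError("posterior_threshold must be in [0, 1]")
    missing = set(dataset.individuals) - set(result.assignment)
    if missing:
        raise ValidationError(f"result lacks calls for individuals {sorted(missing)}")

    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# locus={dataset.locus_id}\n")
        fh.write(f"# ploidy={result.m}\n")
        fh.write(f"# sigma={result.sigma:.6g}\n")
        fh.write(f"# theta={result.theta}\n")
        fh.write(f"# config_posterior={result.config_posterior:.6g}\n")
        fh.write(f"# posterior_threshold={posterior_threshold:.6g}\n")
        fh.write("individual\tdosage\tposterior\tincluded\n")
        for ind in dataset.individuals:
            g = result.assignment[ind]
            post = float(result.individual_posteriors[ind][g])
            included = post >= posterior_threshold
            fh.write(f"{ind}\t{g}\t{post:.6g}\t{int(included)}\n")
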