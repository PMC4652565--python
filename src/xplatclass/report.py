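"""Benchmark report container.

A report is a grid of cells, one per (classifier, selector, representation,
feature count) combination, each holding the test-set accuracy on the 0-100
percent scale.  The TSV rendering mirrors the field's usual benchmark tables:
one row per classifier, one column per selector x representation, best cell
formatted ``ACC (N)`` with the accuracy to one decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple


@dataclass
class CellResult:
    classifier: str
    selector: str
    representation: str
    n_features: int
    accuracy: float  # percent, 0-100
    snsp: Optional[dict] = None  # {class: {"Sn": float|None, "Sp": float|None}}

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier,
            "selector": self.selector,
            "representation": self.representation,
            "n_features": int(self.n_features),
            "accuracy": float(self.accuracy),
        }
        if self.snsp is not None:
            d["snsp"] = self.snsp
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CellResult":
        return cls(
            classifier=d["classifier"],
            selector=d["selector"],
            representation=d["representation"],
            n_features=int(d["n_features"]),
            accuracy=float(d["accuracy"]),
            snsp=d.get("snsp"),
        )


def format_cell(accuracy: float, n_features: int) -> str:
    """Render one grid cell as ``"97.6 (1000)"``."""
    return f"{accuracy:.1f} ({n_features})"


@dataclass
class EvalReport:
    cells: List[CellResult] = field(default_factory=list)

    def best_cells(self) -> Dict[Tuple[str, str, str], CellResult]:
        """Best cell per (classifier, selector, representation).

        Best = maximum accuracy; ties broken by the smaller feature count.
        """
        best: Dict[Tuple[str, str, str], CellResult] = {}
        for cell in self.cells:
            key = (cell.classifier, cell.selector, cell.representation)
            cur = best.get(key)
            if (
                cur is None
                or cell.accuracy > cur.accuracy
                or (cell.accuracy == cur.accuracy and cell.n_features < cur.n_features)
            ):
                best[key] = cell
        return best

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {"cells": [c.to_dict() for c in self.cells]}

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(cells=[CellResult.from_dict(c) for c in d.get("cells", [])])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "EvalReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_grid_tsv(self, path) -> None:
        best = self.best_cells()
        classifiers: List[str] = []
        columns: List[Tuple[str, str]] = []
        for cell in self.cells:
            if cell.classifier not in classifiers:
                classifiers.append(cell.classifier)
            col = (cell.selector, cell.representation)
            if col not in columns:
                columns.append(col)
        lines = ["\t".join(["classifier"] + [f"{s}:{r}" for s, r in columns])]
        for clf in classifiers:
            row = [clf]
            for sel, rep in columns:
                cell = best.get((clf, sel, rep))
                row.append("" if cell is None else format_cell(cell.accuracy, cell.n_features))
            lines.append("\t".join(row))
        Path(path).write_text("\n".join(lines) + "\n")

    def __eq__(self, other) -> bool:  # value equality for round-trip checks
        if not isinstance(other, EvalReport):
            return NotImplemented
        return self.to_dict() == other.to_dict()
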