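"""Common result container for the supplementation screens."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one supplementation screen.

    ``table`` holds the per-compound (and, where applicable, per-species)
    baseline/supplemented values, effects and test statistics; ``selected`` is
    the set of compounds passing the screen's selection rule.
    """

    table: pd.DataFrame
    selected: frozenset = field(default_factory=frozenset)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
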