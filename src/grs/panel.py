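"""SNP risk panel: the per-variant weights behind the gene scores.

A panel row carries the variant identity, its risk allele, the published
per-allele odds ratio and the genetic model under which it is scored.  The
score weight is always ``ln(odds_ratio)`` and is derived at load time so a
panel file can never ship an inconsistent weight.

The package ships the 19-variant coronary heart disease panel used for the
19-SNP score; 13 of its entries form the GWAS-consortium subset used for the
13-SNP score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "SnpPanelEntry",
    "SnpPanel",
    "PanelError",
    "load_panel",
    "default_panel",
    "RSID_ALIASES",
]

#: Input rsids accepted as aliases of a canonical panel rsid.  rs646776 was
#: the originally reported SORT1 variant; the panel genotypes its close proxy
#: rs599839 instead.
RSID_ALIASES = {"rs646776": "rs599839"}

GENETIC_MODELS = ("additive", "recessive")


class PanelError(ValueError):
    """Raised for malformed or internally inconsistent panel definitions."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One scored variant: identity, risk allele, weight and model."""

    rsid: str
    locus: str
    risk_allele: str
    odds_ratio: float
    genetic_model: str
    in_13_panel: bool
    note: str | None = None
    weight: float = field(init=False)

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise PanelError(
                f"{self.rsid}: odds ratio must be positive, got {self.odds_ratio}"
            )
        if self.genetic_model not in GENETIC_MODELS:
            raise PanelError(
                f"{self.rsid}: unknown genetic model {self.genetic_model!r}"
            )
        if len(self.risk_allele) != 1 or self.risk_allele not in "ACGT":
            raise PanelError(
                f"{self.rsid}: risk allele must be a single nucleotide, "
                f"got {self.risk_allele!r}"
            )
        object.__setattr__(self, "weight", math.log(self.odds_ratio))


class SnpPanel:
    """An ordered collection of :class:`SnpPanelEntry` with unique rsids."""

    def __init__(self, entries: Iterable[SnpPanelEntry]):
        self.entries: tuple[SnpPanelEntry, ...] = tuple(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.rsid in seen:
                raise PanelError(f"duplicate rsid in panel: {e.rsid}")
            seen.add(e.rsid)
        self._by_rsid = {e.rsid: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SnpPanelEntry]:
        return iter(self.entries)

    def __getitem__(self, rsid: str) -> SnpPanelEntry:
        return self._by_rsid[RSID_ALIASES.get(rsid, rsid)]

    def __contains__(self, rsid: str) -> bool:
        return RSID_ALIASES.get(rsid, rsid) in self._by_rsid

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    def subset(self, size: int) -> "SnpPanel":
        """Return the full 19-SNP panel or the order-preserving 13-SNP subset."""
        if size == 19 or size == len(self.entries):
            return self
        if size == 13:
            return SnpPanel(e for e in self.entries if e.in_13_panel)
        raise PanelError(f"panel subset must be 19 or 13, got {size}")


def _parse_bool(text: str, where: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise PanelError(f"{where}: cannot parse boolean {text!r}")


def load_panel(path: str | Path) -> SnpPanel:
    """Read a tab-separated panel file.

    The file must carry the header columns ``rsid``, ``locus``,
    ``risk_allele``, ``odds_ratio``, ``model`` and ``in_13_panel`` (an
    optional trailing ``note`` column is kept as an annotation).  Lines
    starting with ``#`` are comments.  Weights are recomputed as
    ``ln(odds_ratio)``; they are not read from the file.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise PanelError(f"{path}: empty panel file")
    header = [c.strip() for c in rows[0]]
    required = ["rsid", "locus", "risk_allele", "odds_ratio", "model", "in_13_panel"]
    missing = [c for c in required if c not in header]
    if missing:
        raise PanelError(f"{path}: missing panel columns {missing}")
    idx = {c: header.index(c) for c in header}
    entries = []
    for lineno, row in enumerate(rows[1:], start=2):
        def cell(col: str) -> str:
            i = idx[col]
            return row[i].strip() if i < len(row) else ""

        rsid = cell("rsid")
        where = f"{path}:{lineno} ({rsid or 'missing rsid'})"
        try:
            odds_ratio = float(cell("odds_ratio"))
        except ValueError:
            raise PanelError(f"{where}: odds_ratio is not a number") from None
        note = cell("note") if "note" in idx else ""
        try:
            entries.append(
                SnpPanelEntry(
                    rsid=rsid,
                    locus=cell("locus"),
                    risk_allele=cell("risk_allele"),
                    odds_ratio=odds_ratio,
                    genetic_model=cell("model"),
                    in_13_panel=_parse_bool(cell("in_13_panel"), where),
                    note=note or None,
                )
            )
        except PanelError as err:
            raise PanelError(f"{where}: {err}") from None
    return SnpPanel(entries)


def default_panel() -> SnpPanel:
    """The shipped 19-SNP coronary heart disease panel."""
    ref = resources.files("grs.data").joinpath("panel_19snp.tsv")
    with resources.as_file(ref) as path:
        return load_panel(path)
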