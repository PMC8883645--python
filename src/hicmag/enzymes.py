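"""Restriction-enzyme recognition motifs for site counting."""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def load_enzyme_table(path: str | Path | None = None) -> dict[str, str]:
    """Enzyme name -> motif map from the shipped config, plus a user table.

    Both files are two-column whitespace-separated text; a user-supplied
    table extends or overrides the shipped one.
    """
    table: dict[str, str] = {}

    def parse(text: str) -> None:
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, motif = line.split()
            table[name] = motif.upper()

    parse(resources.files("hicmag").joinpath("data/enzymes.tsv").read_text())
    if path is not None:
        parse(Path(path).read_text())
    return table


def motifs_for(names: list[str], table: dict[str, str] | None = None) -> list[str]:
    table = table or load_enzyme_table()
    unknown = [n for n in names if n not in table]
    if unknown:
        raise KeyError(
            f"unknown enzyme {unknown[0]!r}; known: {', '.join(sorted(table))}"
        )
    return [table[n] for n in names]
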