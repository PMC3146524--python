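"""Controlled vocabulary of body-fluid labels.

Predictions are made over a fixed, ordered set of body-fluid compartments,
each identified by a positive integer type number and a human-readable name.
The default vocabulary is the 11 human body fluids of the curated secretome
benchmark (1 = Amniotic fluid ... 11 = Urine).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable


@dataclass(frozen=True)
class FluidVocabulary:
    """Ordered mapping between fluid type numbers and fluid names.

    Parameters
    ----------
    entries
        Tuple of ``(type_number, name)`` pairs. Type numbers must be unique
        positive integers sorted ascending; names must be unique.
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("vocabulary must contain at least one fluid")
        numbers = [num for num, _ in self.entries]
        names = [name for _, name in self.entries]
        if any(num <= 0 for num in numbers):
            raise ValueError("fluid type numbers must be positive integers")
        if len(set(numbers)) != len(numbers):
            raise ValueError("duplicate fluid type numbers in vocabulary")
        if numbers != sorted(numbers):
            raise ValueError("fluid type numbers must be sorted ascending")
        if len(set(names)) != len(names):
            raise ValueError("duplicate fluid names in vocabulary")

    @property
    def F(self) -> int:
        """Number of fluids (the label-space size)."""
        return len(self.entries)

    @property
    def numbers(self) -> tuple[int, ...]:
        return tuple(num for num, _ in self.entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for _, name in self.entries)

    def name_of(self, number: int) -> str:
        return self.entries[self.index_of(number)][1]

    def index_of(self, number: int) -> int:
        """Zero-based column index of a fluid number in score vectors."""
        try:
            return self.numbers.index(number)
        except ValueError:
            raise KeyError(f"fluid type number {number} not in vocabulary") from None

    def __contains__(self, number: int) -> bool:
        return number in self.numbers

    def resolve(self, token: str) -> int:
        """Map a fluid token (type number or name) to its type number."""
        token = token.strip()
        if not token:
            raise KeyError("empty fluid token")
        try:
            number = int(token)
        except ValueError:
            for num, name in self.entries:
                if name == token:
                    return num
            raise KeyError(f"unknown fluid name {token!r}") from None
        if number not in self:
            raise KeyError(f"fluid type number {number} not in vocabulary")
        return number

    def validate_fluids(self, fluids: Iterable[int]) -> frozenset[int]:
        fluids = frozenset(int(f) for f in fluids)
        unknown = fluids - set(self.numbers)
        if unknown:
            raise KeyError(f"fluid numbers {sorted(unknown)} not in vocabulary")
        return fluids


@lru_cache(maxsize=1)
def default_vocabulary() -> FluidVocabulary:
    """The 11-fluid human body-fluid vocabulary shipped with the package."""
    path = resources.files("fluidvote.data") / "fluid_vocabulary.tsv"
    return _parse_vocab_lines(path.read_text().splitlines())


def read_fluid_vocab(path: str | Path | None = None) -> FluidVocabulary:
    """Read a fluid vocabulary from a 2-column TSV, or return the default.

    The file has columns (type_number, name); a header line is detected by a
    non-integer first field. ``path=None`` returns the built-in 11-fluid
    vocabulary.
    """
    if path is None:
        return default_vocabulary()
    return _parse_vocab_lines(Path(path).read_text().splitlines())


def _parse_vocab_lines(lines: list[str]) -> FluidVocabulary:
    entries: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split(None, 1)
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected (type_number, name), got {line!r}")
        first = fields[0].strip()
        try:
            number = int(first)
        except ValueError:
            if lineno == 1 or not entries:
                continue  # header line
            raise ValueError(f"line {lineno}: non-integer fluid number {first!r}") from None
        entries.append((number, fields[1].strip()))
    entries.sort(key=lambda e: e[0])
    return FluidVocabulary(tuple(entries))
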