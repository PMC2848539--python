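"""Packaged benchmark fixtures and their loaders.

The package ships two plain-text fixtures:

* ``data/benchmark_complexes.txt`` — the two-chain complex benchmark list,
  one 6-character entry per complex (4-character PDB code + the two
  interacting chain IDs).
* ``data/top_models.tsv`` — printed parameters of the partial models built
  from full-interface-coverage alignments at 40% maximum target coverage
  (top-model rows plus alternative best-model rows flagged ``alternative``).
"""

from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .errors import ParameterError

__all__ = ["load_complex_list", "benchmark_complexes", "top_models_table"]

_ENTRY_RE = re.compile(r"^[0-9a-zA-Z]{4}[A-Za-z0-9]{2}$")


def load_complex_list(path) -> list[tuple[str, str, str]]:
    """Parse a complex list file into (pdb_code, chain_a, chain_b) tuples.

    Entries are whitespace-separated 6-character tokens; lines starting with
    '#' are comments. Duplicate entries and entries whose two chain IDs
    coincide are rejected.
    """
    entries: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for token in line.split():
                if not _ENTRY_RE.match(token):
                    raise ParameterError(
                        f"line {lineno}: malformed entry {token!r} "
                        "(expected 4-char code + 2 chain IDs)"
                    )
                if token in seen:
                    raise ParameterError(f"line {lineno}: duplicate entry {token!r}")
                code, ca, cb = token[:4], token[4], token[5]
                if ca == cb:
                    raise ParameterError(
                        f"line {lineno}: entry {token!r} has identical chain IDs"
                    )
                seen.add(token)
                entries.append((code, ca, cb))
    return entries


def _data_path(name: str):
    return resources.files("ifacecov").joinpath("data", name)


def benchmark_complexes() -> list[tuple[str, str, str]]:
    """The packaged two-chain complex benchmark list."""
    with resources.as_file(_data_path("benchmark_complexes.txt")) as p:
        return load_complex_list(p)


def top_models_table() -> pd.DataFrame:
    """The packaged partial-model results table.

    Columns: target, template, log_e, q, q_dom, a_iden, a_sim, i_iden, i_sim,
    interface_rmsd, alternative (1 = alternative best-model row, not a top
    model).
    """
    with resources.as_file(_data_path("top_models.tsv")) as p:
        return pd.read_csv(p, sep="\t")
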