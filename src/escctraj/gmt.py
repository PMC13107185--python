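"""Reading and writing gene/protein set collections in GMT format.

One set per line: name <TAB> description <TAB> member IDs...  A collection
is an ordered dict mapping set name -> list of member IDs; descriptions are
kept separately.
"""

from __future__ import annotations

import warnings


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >=3 fields")
            name, _desc, members = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            if not members:
                warnings.warn(f"skipping empty set {name!r}")
                continue
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
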