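"""Readers and writers for matrices and trees.

Matrices travel as CSV (area row label + one column per character, the
layout of the shipped fixtures), NEXUS characters blocks, or TNT xread
(symbols "01", outgroup first).  Trees are written as Newick (one per
line) or a NEXUS trees block; parsing goes through dendropy.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .matrix import MatrixError, PresenceMatrix
from .parsimony import TreeSet

__all__ = ["read_matrix", "write_matrix", "write_trees", "read_trees"]


def read_matrix(
    path: str | Path,
    dialect: str = "csv",
    outgroup: str | None = None,
    add_outgroup_if_missing: bool = False,
) -> PresenceMatrix:
    """Read a presence/absence matrix.

    The outgroup row is detected as the (unique) all-zero row when
    ``outgroup`` is not named explicitly.  A matrix without any all-zero
    row is rejected unless ``add_outgroup_if_missing`` is set, in which
    case a synthetic "Outgroup" row is appended.
    """
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path, index_col=0)
    elif dialect == "nexus":
        df = _parse_nexus(path)
    elif dialect == "tnt":
        df = _parse_tnt(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    bad = df.map(lambda v: v not in (0, 1))
    if bad.to_numpy().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise MatrixError(
            f"non-binary symbol at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if outgroup is None:
        zero_rows = [i for i in df.index if not df.loc[i].any()]
        if len(zero_rows) == 1:
            outgroup = zero_rows[0]
        elif zero_rows:
            raise MatrixError(f"several all-zero rows, name the outgroup: {zero_rows}")
        elif add_outgroup_if_missing:
            outgroup = "Outgroup"
            df.loc[outgroup] = 0
            df = df.loc[[outgroup] + [i for i in df.index if i != outgroup]]
        else:
            raise MatrixError(
                "no all-zero outgroup row found "
                "(pass add_outgroup_if_missing=True to append one)"
            )
    return PresenceMatrix(df, outgroup=outgroup)


def write_matrix(matrix: PresenceMatrix, path: str | Path, dialect: str = "csv") -> None:
    path = Path(path)
    if dialect == "csv":
        out = matrix.data.copy()
        out.index.name = "area"
        out.to_csv(path)
    elif dialect == "nexus":
        path.write_text(_format_nexus(matrix))
    elif dialect == "tnt":
        path.write_text(_format_tnt(matrix))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _sanitize(label: str) -> str:
    return label.replace(" ", "_")


def _format_nexus(matrix: PresenceMatrix) -> str:
    n, c = matrix.shape
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={n} NCHAR={c};",
        '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    width = max(len(_sanitize(a)) for a in matrix.areas) + 2
    for area in matrix.areas:
        row = "".join(str(v) for v in matrix.data.loc[area])
        lines.append(f"    {_sanitize(area):<{width}}{row}")
    lines += ["  ;", "END;", ""]
    lines.insert(1, "[characters: " + " ".join(_sanitize(ch) for ch in matrix.characters) + "]")
    return "\n".join(lines)


def _parse_nexus(path: Path) -> pd.DataFrame:
    import dendropy

    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    rows = {}
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        rows[taxon.label.replace(" ", "_")] = [int(str(s)) for s in seq]
    text = path.read_text()
    chars = None
    for line in text.splitlines():
        if line.strip().startswith("[characters:"):
            chars = line.strip()[len("[characters:") : -1].split()
            break
    df = pd.DataFrame.from_dict(rows, orient="index")
    if chars and len(chars) == df.shape[1]:
        df.columns = chars
    else:
        df.columns = [f"char{i+1}" for i in range(df.shape[1])]
    return df


def _format_tnt(matrix: PresenceMatrix) -> str:
    n, c = matrix.shape
    # outgroup first: TNT roots on the first taxon
    areas = [matrix.outgroup] + [a for a in matrix.areas if a != matrix.outgroup]
    width = max(len(_sanitize(a)) for a in areas) + 2
    lines = ["xread", f"'{c} characters, {n} areas'", f"{c} {n}"]
    for area in areas:
        row = "".join(str(v) for v in matrix.data.loc[area])
        lines.append(f"{_sanitize(area):<{width}}{row}")
    lines += [";", ""]
    return "\n".join(lines)


def _parse_tnt(path: Path) -> pd.DataFrame:
    lines = [l.rstrip() for l in Path(path).read_text().splitlines()]
    if not lines or lines[0].strip() != "xread":
        raise MatrixError("not a TNT xread file")
    i = 1
    while lines[i].strip().startswith("'"):
        i += 1
    nchar, ntax = (int(x) for x in lines[i].split())
    rows = {}
    for line in lines[i + 1 :]:
        line = line.strip()
        if not line or line == ";":
            continue
        name, seq = line.rsplit(None, 1)
        rows[name] = [int(ch) for ch in seq]
        if len(seq) != nchar:
            raise MatrixError(f"row {name!r} has {len(seq)} of {nchar} symbols")
    if len(rows) != ntax:
        raise MatrixError(f"expected {ntax} rows, found {len(rows)}")
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"char{i+1}" for i in range(nchar)]
    return df


def write_trees(trees: TreeSet, path: str | Path, root_label: str | None = None,
                schema: str = "newick") -> None:
    path = Path(path)
    newicks = trees.to_newick(root_label)
    if schema == "newick":
        path.write_text("\n".join(newicks) + "\n")
    elif schema == "nexus":
        lines = ["#NEXUS", "BEGIN TREES;"]
        for i, nwk in enumerate(newicks, start=1):
            lines.append(f"  TREE mpt_{i} = {nwk}")
        lines += ["END;", ""]
        path.write_text("\n".join(lines))
    else:
        raise ValueError(f"unknown schema {schema!r}")


def read_trees(path: str | Path, labels: list[str]):
    """Newick file (one tree per line) onto a fixed leaf-label universe."""
    from .trees import AreaTree

    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(AreaTree.from_newick(line, labels))
    return out
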