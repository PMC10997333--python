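"""Context-free dependency parses of the stimulus sentences.

A sentence's structure is represented as a rooted dependency tree: every
word (dependent) points at its syntactic head, the main verb is the root.
The *parse depth* of a word is the number of edges between it and the root
(root = 0).  For the temporarily ambiguous target sentences two trees
coexist until the actual main verb arrives: a *passive* parse in which the
first verb heads a reduced relative clause attached to the subject noun,
and an *active* parse in which the first verb is itself the main verb.

Parse-depth vectors of the first three words (determiner, subject noun,
first verb) serve as fixed landmarks of the two interpretations in the 3-D
model space used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ROOT = 0  # HEAD value marking the root token, as in CoNLL-U

VALID_INTERPRETATIONS = ("passive", "active", "other")


class TreeStructureError(ValueError):
    """Raised when a head assignment does not define a valid rooted tree."""


@dataclass(frozen=True)
class DependencyTree:
    """A validated rooted dependency tree over one sentence.

    Token positions are 1-based; ``head[i]`` gives the 1-based head of
    token ``i + 1``, with 0 marking the root.
    """

    tokens: tuple[str, ...]
    head: tuple[int, ...]
    interpretation_label: str = "other"
    sentence_id: str = ""
    deprel: tuple[str, ...] = ()

    @property
    def n_tokens(self) -> int:
        return len(self.tokens)

    @property
    def root_position(self) -> int:
        """1-based position of the root token."""
        return self.head.index(ROOT) + 1

    def __post_init__(self) -> None:
        if self.interpretation_label not in VALID_INTERPRETATIONS:
            raise ValueError(
                f"interpretation_label must be one of {VALID_INTERPRETATIONS}, "
                f"got {self.interpretation_label!r}"
            )
        _validate_heads(self.tokens, self.head)


@dataclass(frozen=True)
class ParseDepthVector:
    """Per-word parse depths for an incremental sentence prefix.

    ``source`` distinguishes integer context-free depths read off a
    dependency tree from the non-negative real depths estimated by the
    structural probe.
    """

    sentence_id: str
    depths: tuple[float, ...]
    source: str = "context_free"  # or "probe"

    @property
    def prefix_len(self) -> int:
        return len(self.depths)

    def __post_init__(self) -> None:
        if self.source not in ("context_free", "probe"):
            raise ValueError(f"unknown source {self.source!r}")
        arr = np.asarray(self.depths, dtype=float)
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
            raise ValueError("depths must be finite and non-negative")
        if self.source == "context_free" and arr.size and np.any(arr != np.round(arr)):
            raise ValueError("context-free depths must be integers")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.depths, dtype=float)


def _validate_heads(tokens: Sequence[str], head: Sequence[int]) -> None:
    n = len(tokens)
    if n == 0:
        raise TreeStructureError("empty sentence")
    if len(head) != n:
        raise TreeStructureError(f"{len(head)} heads for {n} tokens")
    roots = [i + 1 for i, h in enumerate(head) if h == ROOT]
    if len(roots) != 1:
        raise TreeStructureError(
            f"exactly one root required, found {len(roots)} "
            f"(tokens {', '.join(tokens[r - 1] for r in roots) or 'none'})"
        )
    for i, h in enumerate(head):
        if not (0 <= h <= n):
            raise TreeStructureError(
                f"token {i + 1} ({tokens[i]!r}) has out-of-range head index {h}"
            )
        if h == i + 1:
            raise TreeStructureError(f"token {i + 1} ({tokens[i]!r}) is its own head")
    # Walk from every token to the root; revisiting a token means a cycle.
    for start in range(1, n + 1):
        seen = set()
        pos = start
        while pos != ROOT:
            if pos in seen:
                raise TreeStructureError(
                    f"cycle involving token {pos} ({tokens[pos - 1]!r})"
                )
            seen.add(pos)
            pos = head[pos - 1]


def build_tree(
    tokens: Sequence[str],
    head_assignment: Sequence[int],
    *,
    interpretation_label: str = "other",
    sentence_id: str = "",
    deprel: Sequence[str] | None = None,
) -> DependencyTree:
    """Build and validate a dependency tree from a head assignment.

    Raises :class:`TreeStructureError` naming the offending token on
    multiple roots, cycles, or out-of-range head indices.
    """
    return DependencyTree(
        tokens=tuple(tokens),
        head=tuple(int(h) for h in head_assignment),
        interpretation_label=interpretation_label,
        sentence_id=sentence_id,
        deprel=tuple(deprel) if deprel is not None else (),
    )


def node_depths(tree: DependencyTree) -> ParseDepthVector:
    """Context-free parse depth of every token: edges to the root.

    depth(root) = 0 and depth(w) = depth(head(w)) + 1.
    """
    depths = [-1] * tree.n_tokens

    def depth_of(pos: int) -> int:
        if tree.head[pos - 1] == ROOT:
            return 0
        if depths[pos - 1] < 0:
            depths[pos - 1] = depth_of(tree.head[pos - 1]) + 1
        return depths[pos - 1]

    return ParseDepthVector(
        sentence_id=tree.sentence_id,
        depths=tuple(float(depth_of(p)) for p in range(1, tree.n_tokens + 1)),
        source="context_free",
    )


def landmark_vector(tree: DependencyTree, prefix_len: int) -> ParseDepthVector:
    """Depths of the first ``prefix_len`` words of the full parse.

    The landmark of an interpretation for a given prefix is static: the
    whole-sentence tree's depths sliced to the prefix.  With
    ``prefix_len = 3`` this yields the (determiner, subject-noun, Verb1)
    landmark, (2, 1, 2) for the passive and (2, 1, 0) for the active parse
    of the target sentences.
    """
    if not 1 <= prefix_len <= tree.n_tokens:
        raise ValueError(
            f"prefix_len {prefix_len} out of range 1..{tree.n_tokens}"
        )
    full = node_depths(tree)
    return ParseDepthVector(
        sentence_id=tree.sentence_id,
        depths=full.depths[:prefix_len],
        source="context_free",
    )


# ---------------------------------------------------------------------------
# CoNLL-U I/O (ID, FORM, HEAD, DEPREL columns; other columns preserved as _)
# ---------------------------------------------------------------------------

_CONLLU_COLS = 10


def read_conllu(path: str | Path) -> list[DependencyTree]:
    """Read dependency trees from a CoNLL-U file.

    Multiword-token and empty-node lines (ranged or decimal IDs) are not
    supported; sentence metadata ``# sent_id`` and ``# interpretation``
    comments populate the corresponding tree fields.
    """
    trees: list[DependencyTree] = []
    tokens: list[str] = []
    heads: list[int] = []
    deprels: list[str] = []
    sent_id = ""
    label = "other"

    def flush() -> None:
        nonlocal tokens, heads, deprels, sent_id, label
        if tokens:
            trees.append(
                build_tree(
                    tokens,
                    heads,
                    interpretation_label=label,
                    sentence_id=sent_id,
                    deprel=deprels,
                )
            )
        tokens, heads, deprels = [], [], []
        sent_id, label = "", "other"

    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sent_id"):
                sent_id = body.split("=", 1)[1].strip()
            elif body.startswith("interpretation"):
                label = body.split("=", 1)[1].strip()
            continue
        fields = line.split("\t")
        if len(fields) < 8:
            raise ValueError(f"malformed CoNLL-U line: {line!r}")
        tok_id = fields[0]
        if "-" in tok_id or "." in tok_id:
            raise ValueError(f"unsupported CoNLL-U token id {tok_id!r}")
        expected = len(tokens) + 1
        if int(tok_id) != expected:
            raise ValueError(f"non-contiguous token id {tok_id} (expected {expected})")
        tokens.append(fields[1])
        heads.append(int(fields[6]))
        deprels.append(fields[7])
    flush()
    return trees


def write_conllu(trees: Iterable[DependencyTree], path: str | Path) -> None:
    lines: list[str] = []
    for tree in trees:
        if tree.sentence_id:
            lines.append(f"# sent_id = {tree.sentence_id}")
        lines.append(f"# interpretation = {tree.interpretation_label}")
        deprels = tree.deprel or ("_",) * tree.n_tokens
        for i, (tok, head, rel) in enumerate(zip(tree.tokens, tree.head, deprels), 1):
            row = [str(i), tok, "_", "_", "_", "_", str(head), rel, "_", "_"]
            lines.append("\t".join(row))
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")
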