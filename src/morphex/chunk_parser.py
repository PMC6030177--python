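"""Heuristic dependency trees for tagged chunks.

The annotation rules are phrased over a chunk's dependency tree: a rule looks
at a node's role and its neighbours (ancestor, siblings, children).  Rather
than requiring an external parser binary, this module builds the minimal tree
shapes those rules consume, from the tag sequence alone:

* the head is the leftmost entity (E), else the leftmost state (A), else the
  leftmost numeral (Z), else the first token — chunks overwhelmingly describe
  one structure and its states;
* states and numerals hang off the head as siblings;
* an adverb attaches to the nearest following content token, else the nearest
  preceding one;
* parenthetical tokens attach under the token just before the parenthesis;
* a preposition or verb opens a subtree that captures everything after it;
* in a coordination the conjunction hangs under the first conjunct and later
  conjuncts become its siblings.

Any backend satisfying these attachment contracts (``parse``'s
postconditions) can replace this one; the rule engine only consumes the
relations exposed by :func:`neighbors`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core_model import Chunk, Token

CONTENT_TAGS = frozenset("AVZUER")


class MalformedChunkError(ValueError):
    """Raised when asked to parse a chunk with no tokens."""


@dataclass
class DepNode:
    token: Token
    parent: Optional["DepNode"] = None
    children: list["DepNode"] = field(default_factory=list)

    def attach(self, child: "DepNode") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"DepNode({self.token.surface}/{self.token.tag})"


def parse(chunk: Chunk) -> DepNode:
    """Build the dependency tree of a tagged chunk; returns the root node."""
    tokens = chunk.tokens
    if not tokens:
        raise MalformedChunkError(f"chunk {chunk.id} has no tokens")

    nodes = [DepNode(t) for t in tokens]
    root = _pick_root(tokens, nodes)

    # container: where non-adverb tokens attach (root, or the open S/V node)
    container = root
    last_top_level: Optional[DepNode] = None  # anchor for parentheticals
    first_conjunct: Optional[DepNode] = None
    pending_conjunction = False

    for node in nodes:
        tok = node.token
        if node is root:
            last_top_level = node
            first_conjunct = None
            pending_conjunction = False
            continue
        if tok.in_parens:
            continue  # attached in the second pass
        if tok.tag == "R":
            last_top_level = node
            continue  # attached in the second pass
        if tok.tag in ("S", "V"):
            container.attach(node)
            container = node
            first_conjunct = None
            pending_conjunction = False
        elif tok.tag == "C":
            first_conjunct = last_top_level
            if first_conjunct is not None and first_conjunct is not node:
                first_conjunct.attach(node)
            else:
                container.attach(node)
            pending_conjunction = True
        elif pending_conjunction and first_conjunct is not None:
            # later conjunct: sibling of the first conjunct
            target = first_conjunct.parent or first_conjunct
            target.attach(node)
            pending_conjunction = False
        else:
            container.attach(node)
        last_top_level = node

    _attach_parentheticals(nodes)
    _attach_adverbs(nodes, root)
    return root


def _pick_root(tokens: list[Token], nodes: list[DepNode]) -> DepNode:
    for want in ("E", "A", "Z"):
        for t, n in zip(tokens, nodes):
            if t.tag == want and not t.in_parens:
                return n
    return nodes[0]


def _attach_parentheticals(nodes: list[DepNode]) -> None:
    anchor: Optional[DepNode] = None
    for node in nodes:
        if node.token.in_parens:
            if anchor is not None and anchor is not node:
                anchor.attach(node)
            elif node.parent is None and nodes[0] is not node:
                nodes[0].attach(node)
        else:
            anchor = node


def _attach_adverbs(nodes: list[DepNode], root: DepNode) -> None:
    for i, node in enumerate(nodes):
        if node.token.tag != "R" or node is root or node.token.in_parens:
            continue
        target = None
        for other in nodes[i + 1 :]:
            if other.token.tag in CONTENT_TAGS and not other.token.in_parens:
                target = other
                break
        if target is None:
            # backward fallback skips other adverbs: a pair of trailing
            # adverbs pointing at each other would make the tree cyclic
            for other in reversed(nodes[:i]):
                if (
                    other.token.tag in CONTENT_TAGS - {"R"}
                    and not other.token.in_parens
                ) or other is root:
                    target = other
                    break
        (target if target is not None else root).attach(node)


def neighbors(
    node: DepNode,
) -> tuple[Optional[DepNode], list[DepNode], list[DepNode]]:
    """The (ancestor, siblings, children) relations the adverb rules test."""
    ancestor = node.parent
    siblings = (
        [n for n in node.parent.children if n is not node] if node.parent else []
    )
    return ancestor, siblings, list(node.children)


def to_bracket(node: DepNode) -> str:
    """One-line bracketed rendering, for golden-file tests and debugging."""
    if not node.children:
        return f"({node.token.surface}/{node.token.tag})"
    inner = " ".join(to_bracket(c) for c in node.children)
    return f"({node.token.surface}/{node.token.tag} {inner})"


def check_tree(root: DepNode, chunk: Chunk) -> list[str]:
    """Verify tree invariants: single root, acyclic, covers all tokens."""
    problems = []
    seen: set[int] = set()
    stack = [root]
    while stack:
        n = stack.pop()
        if id(n) in seen:
            problems.append("cycle detected")
            break
        seen.add(id(n))
        stack.extend(n.children)
    if root.parent is not None:
        problems.append("root has a parent")
    if len(seen) != len(chunk.tokens):
        problems.append(
            f"tree covers {len(seen)} nodes for {len(chunk.tokens)} tokens"
        )
    return problems
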