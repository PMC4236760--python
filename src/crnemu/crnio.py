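"""Plain-text ``.crn`` reaction-list format.

One reaction per line, ``complex ->{rate} complex``.  A complex is ``0``
(empty) or ``+``-separated terms; a term is ``Name``, ``nName`` or
``n*Name`` with ``n`` a positive integer.  ``#`` starts a comment.  An
optional header line ``species: A B C`` fixes the species order (complex
species not listed are appended in first-mention order).

Example::

    species: A B C
    # dimerisation feeding C
    2A + B ->{1.5} B + C
    0 ->{2} A
"""

from __future__ import annotations

import re

from .network import Complex, CRNError, Reaction, ReactionNetwork, make_network

__all__ = ["parse_crn", "write_crn", "ParseError"]

_TERM_RE = re.compile(r"(?:(\d+)\s*\*?\s*)?([A-Za-z_][A-Za-z0-9_]*)\Z")
_ARROW_RE = re.compile(r"->\{\s*([^}]*)\s*\}")


class ParseError(CRNError):
    """Syntax error in `.crn` text; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _parse_complex(text: str, lineno: int) -> Complex:
    text = text.strip()
    if text == "0":
        return Complex()
    if not text:
        raise ParseError(lineno, "empty complex (use 0 for the empty complex)")
    counts: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if not m:
            raise ParseError(lineno, f"bad complex term {term!r}")
        n = int(m.group(1)) if m.group(1) else 1
        if n <= 0:
            raise ParseError(lineno, f"multiplicity must be positive in {term!r}")
        name = m.group(2)
        counts[name] = counts.get(name, 0) + n
    return Complex(counts)


def parse_crn(text: str) -> ReactionNetwork:
    """Parse `.crn` text into a network (duplicates merged, rates > 0)."""
    species_order: list[str] = []
    reactions: list[Reaction] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("species:"):
            for tok in line[len("species:"):].split():
                if tok in species_order:
                    raise ParseError(lineno, f"species {tok!r} listed twice")
                species_order.append(tok)
            continue
        m = _ARROW_RE.search(line)
        if not m:
            raise ParseError(lineno, f"expected 'complex ->{{rate}} complex' in {line!r}")
        lhs, rhs = line[: m.start()], line[m.end():]
        try:
            rate = float(m.group(1))
        except ValueError:
            raise ParseError(lineno, f"bad rate {m.group(1)!r}") from None
        if not rate > 0:
            raise ParseError(lineno, f"rate must be > 0, got {m.group(1)}")
        reactants = _parse_complex(lhs, lineno)
        products = _parse_complex(rhs, lineno)
        reactions.append(Reaction(reactants, products, rate))
    try:
        return make_network(species_order, reactions)
    except CRNError as exc:
        raise ParseError(0, str(exc)) from exc


def _fmt_complex(c: Complex) -> str:
    if not c:
        return "0"
    return " + ".join(
        name if c[name] == 1 else f"{c[name]}{name}" for name in sorted(c)
    )


def write_crn(net: ReactionNetwork) -> str:
    """Serialize a network; ``parse_crn(write_crn(net))`` equals ``net``.

    Rates are written with ``repr`` so round-trips are bit-exact.
    """
    lines = ["species: " + " ".join(net.species)] if net.species else []
    for r in net.reactions:
        lines.append(f"{_fmt_complex(r.reactants)} ->{{{r.rate!r}}} {_fmt_complex(r.products)}")
    return "\n".join(lines) + "\n"
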