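"""Gene-symbol normalization and gene-list field splitting.

Target-gene lists in published component tables mix ASCII commas with the
fullwidth ideographic comma ``、``, and symbol case varies across source
databases. All gene identifiers entering the pipeline pass through
:func:`normalize_symbol` so that set operations (intersection with a disease
gene list, unions across compounds, gene-set membership) compare like with
like.
"""

from __future__ import annotations

import re

from .errors import ParseError

#: Characters that delimit gene lists in tabular sources. The fullwidth comma
#: appears verbatim in tables typeset with CJK punctuation; semicolons occur in
#: some exports.
_DELIMITERS = ",、;"

_DELIM_RE = re.compile(f"[{_DELIMITERS}]")

GeneSymbol = str
"""A normalized gene identifier: uppercased, trimmed, delimiter-free token."""


def normalize_symbol(raw: str, *, context: str | None = None) -> GeneSymbol:
    """Normalize one gene symbol: trim whitespace and uppercase.

    Parameters
    ----------
    raw
        The symbol as it appears in a source file.
    context
        Optional row/file context included in the error message.

    Returns
    -------
    str
        The normalized symbol. Hyphens are preserved (``HLA-A`` is a valid
        symbol); whitespace and list delimiters are rejected.

    Raises
    ------
    ParseError
        If the token is empty after trimming, contains internal whitespace,
        or contains a list-delimiter character.
    """
    token = raw.strip()
    where = f" ({context})" if context else ""
    if not token:
        raise ParseError(f"empty gene symbol{where}")
    if _DELIM_RE.search(token):
        raise ParseError(f"gene symbol {token!r} contains a list delimiter{where}")
    if any(ch.isspace() for ch in token):
        raise ParseError(f"gene symbol {token!r} contains whitespace{where}")
    return token.upper()


def split_gene_field(field: str, *, context: str | None = None) -> list[GeneSymbol]:
    """Split a delimited gene-list field and normalize every token.

    Splits on ASCII comma, fullwidth comma ``、`` and semicolon; empty tokens
    (from trailing or doubled delimiters) are dropped. Order of first
    appearance is preserved; duplicates are kept (callers wanting set
    semantics deduplicate explicitly).
    """
    return [
        normalize_symbol(tok, context=context)
        for tok in _DELIM_RE.split(field)
        if tok.strip()
    ]
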