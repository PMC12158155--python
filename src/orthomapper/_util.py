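"""Small shared helpers: atomic file writes, identifier de-duplication."""

from __future__ import annotations

import os
import tempfile
import warnings
from contextlib import contextmanager
from pathlib import Path

from ._errors import ConversionWarning


@contextmanager
def atomic_path(final_path: str | Path):
    """Yield a temporary path in the same directory; rename onto *final_path* on success.

    Interrupted runs therefore never leave a partially written output file.
    """
    final_path = Path(final_path)
    final_path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=final_path.parent, prefix=f".{final_path.name}.")
    os.close(fd)
    try:
        yield Path(tmp)
        os.replace(tmp, final_path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def make_unique(ids: list[str], kind: str = "feature") -> list[str]:
    """Resolve duplicate identifiers by suffixing repeats with "-1", "-2", ...

    The first occurrence keeps its name; later occurrences get the smallest
    numeric suffix that does not itself collide. Emits one warning per
    duplicated identifier.
    """
    seen: dict[str, int] = {}
    taken = set()
    out = []
    dups = []
    for ident in ids:
        if ident not in taken:
            out.append(ident)
            taken.add(ident)
            seen.setdefault(ident, 0)
            continue
        dups.append(ident)
        n = seen.get(ident, 0)
        while True:
            n += 1
            candidate = f"{ident}-{n}"
            if candidate not in taken:
                break
        seen[ident] = n
        out.append(candidate)
        taken.add(candidate)
    if dups:
        warnings.warn(
            f"{len(dups)} duplicate {kind} id(s) resolved by numeric suffixing "
            f"(e.g. {dups[0]!r})",
            ConversionWarning,
            stacklevel=3,
        )
    return out
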