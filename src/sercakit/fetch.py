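"""Optional cache-aware fetcher for PDB entries (convenience only).

Not part of the tested analysis core: the pipeline consumes whatever
structure files already sit in the structure directory. This helper fills
such a directory from the public archive when a network is available,
skipping files already cached.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

__all__ = ["fetch_pdb", "fetch_corpus"]

_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def fetch_pdb(pdb_id: str, cache_dir: str | Path, timeout: float = 15.0) -> Path:
    """Download one mmCIF entry into ``cache_dir`` (no-op if cached)."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id.lower()}.cif"
    if target.exists() and target.stat().st_size > 0:
        return target
    url = _URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as response:
        data = response.read()
    target.write_bytes(data)
    return target


def fetch_corpus(pdb_ids, cache_dir: str | Path, timeout: float = 15.0) -> dict[str, Path | None]:
    """Fetch a list of entries; failures map to None instead of raising."""
    out: dict[str, Path | None] = {}
    for pdb_id in pdb_ids:
        try:
            out[pdb_id] = fetch_pdb(pdb_id, cache_dir, timeout=timeout)
        except Exception:
            out[pdb_id] = None
    return out
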