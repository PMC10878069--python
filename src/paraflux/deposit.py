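"""Access to the deposited Paracoccus denitrificans Pd1222 model files.

The deposit ships the model as ``Paracoccus_denitrificans.xml`` (SBML)
with companion tab-separated listings ``Paracoccus_reactions.txt`` and
``Paracoccus_metabolites.txt``.  These files are not bundled here (they
are a published artifact, fetched on demand); :func:`fetch_deposit`
downloads them once and :func:`load_deposit` parses a local copy, so every
exact-reproduction computation can be re-run against the genuine model.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .model import MetabolicModel
from .model_io import parse_sbml, parse_tab

DEPOSIT_URL = (
    "https://raw.githubusercontent.com/SergioBordel/ModelParacoccus/master"
)
SBML_FILE = "Paracoccus_denitrificans.xml"
REACTIONS_FILE = "Paracoccus_reactions.txt"
METABOLITES_FILE = "Paracoccus_metabolites.txt"

#: directories probed by :func:`find_deposit`, relative to the cwd
SEARCH_DIRS = ("deposit", "scratch/deposit", "data/deposit")


def fetch_deposit(directory: str | Path, base_url: str = DEPOSIT_URL) -> Path:
    """Download the three deposit files into ``directory`` (needs network)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in (SBML_FILE, REACTIONS_FILE, METABOLITES_FILE):
        urllib.request.urlretrieve(f"{base_url}/{name}", directory / name)
    return directory


def find_deposit(start: str | Path = ".") -> Path | None:
    """Locate a local copy of the deposit under conventional directories."""
    start = Path(start)
    for rel in SEARCH_DIRS:
        cand = start / rel
        if (cand / SBML_FILE).exists() or (cand / REACTIONS_FILE).exists():
            return cand
    return None


def load_deposit(directory: str | Path, prefer: str = "sbml") -> MetabolicModel:
    """Parse a local copy of the deposit (SBML preferred, tab fallback)."""
    directory = Path(directory)
    sbml = directory / SBML_FILE
    tab = directory / REACTIONS_FILE
    if prefer == "sbml" and sbml.exists():
        return parse_sbml(sbml.read_text())
    if tab.exists():
        return parse_tab(
            tab.read_text(), (directory / METABOLITES_FILE).read_text()
        )
    if sbml.exists():
        return parse_sbml(sbml.read_text())
    raise FileNotFoundError(
        f"no deposit model found under {directory}; expected {SBML_FILE} or "
        f"{REACTIONS_FILE} + {METABOLITES_FILE} (see fetch_deposit)"
    )


def find_exchange(model: MetabolicModel, key: str) -> str:
    """Resolve an exchange reaction from its id, its metabolite id, or the
    metabolite name (case-insensitive)."""
    if key in model.reactions and model.reactions[key].is_exchange:
        return key
    low = key.lower()
    for rxn in model.exchanges:
        if len(rxn.stoichiometry) != 1:
            continue
        met = model.metabolites[model.exchange_metabolite(rxn.id)]
        if low in (rxn.id.lower(), met.id.lower(), met.name.lower()):
            return rxn.id
    raise KeyError(f"no exchange reaction matches {key!r}")
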