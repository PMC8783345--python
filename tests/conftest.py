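import hashlib
from pathlib import Path

import pytest

from vesiclink.simulate import generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The default synthetic input tree (seeded), shared across tests."""
    root = tmp_path_factory.mktemp("fixture")
    return generate_fixture(root / "fix", seed=11)


def tree_hash(root) -> dict:
    """sha256 per non-hidden file, keyed by relative path."""
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(root).rglob("*"))
        if p.is_file() and not p.name.startswith(".")
    }


def interaction_set(interactions) -> set:
    """Flatten PredictedInteraction objects to (b, h, cls, dom, start, end)."""
    return {
        (i.bacterial_protein_id, i.host_protein_id, ev.motif_class_id,
         ev.domain_acc, ev.start, ev.end)
        for i in interactions for ev in i.evidence
    }
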