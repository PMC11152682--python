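"""Layer names and the feature-ID prefix convention used when the three
omic layers are concatenated into one feature space."""

PROTEOME = "proteome"
ACETYLOME = "acetylome"
PHOSPHO = "phospho"

LAYERS = (PROTEOME, ACETYLOME, PHOSPHO)

_PREFIX = {PROTEOME: "PROT", ACETYLOME: "ACK", PHOSPHO: "PP"}
_UNPREFIX = {v: k for k, v in _PREFIX.items()}


def prefix_feature(layer: str, feature_id: str) -> str:
    """Tag a feature ID with its layer, e.g. ``ACK:FASN_K673``."""
    return f"{_PREFIX[layer]}:{feature_id}"


def split_feature(prefixed: str) -> tuple[str, str]:
    """Inverse of :func:`prefix_feature` -> (layer, bare feature ID)."""
    tag, _, fid = prefixed.partition(":")
    if not fid or tag not in _UNPREFIX:
        raise ValueError(f"not a layer-prefixed feature ID: {prefixed!r}")
    return _UNPREFIX[tag], fid
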