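"""edd-screen: motif-based dehydratase discrimination and the supporting
pathway-survey, artefact-filter, phylogenetics, and kinetics toolkit."""

from importlib.resources import files as _files

__version__ = "0.1.0"


def data_path(name: str):
    """Path-like handle to a packaged data file."""
    return _files("edd_screen") / "data" / name


__all__ = ["__version__", "data_path"]
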