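"""sentstruct: incremental sentence-structure interpretation analysis.

Tools for studying how a structured interpretation of a temporarily
ambiguous spoken sentence is built word by word: linear structural probing
of contextual embeddings to dependency parse depths, corpus-ratio
constraint indices, interpretation geometry in parse-depth space,
spatiotemporal searchlight representational similarity analysis against
source-space epochs, and NMF + multivariate Granger causality over
model-fit maps — all exercised end to end on synthetic data.
"""

from importlib import resources as _resources

from .trees import (
    DependencyTree,
    ParseDepthVector,
    TreeStructureError,
    build_tree,
    landmark_vector,
    node_depths,
    read_conllu,
    write_conllu,
)

__version__ = "0.1.0"


def example_parse_trees() -> dict[str, DependencyTree]:
    """The packaged passive/active parses of the worked-example sentence
    "The dog found in the park was covered in mud"."""
    with _resources.as_file(
        _resources.files("sentstruct.data") / "example_parses.conllu"
    ) as path:
        trees = read_conllu(path)
    return {t.interpretation_label: t for t in trees}


__all__ = [
    "DependencyTree",
    "ParseDepthVector",
    "TreeStructureError",
    "build_tree",
    "node_depths",
    "landmark_vector",
    "read_conllu",
    "write_conllu",
    "example_parse_trees",
]
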