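"""scikit-learn-style estimator surface.

``ResidueEmbedder`` is a transformer: fit on aligned homolog pairs, transform
sequences into per-residue embedding matrices.  ``ResiduePrefilter`` fits on
a target sequence set (embedding + indexing) and ranks query sequences by the
accumulated noise-gated neighbor score.  Both follow the sklearn parameter
conventions (``get_params`` / ``set_params``, fitted attributes with a
trailing underscore) and clone cleanly for use in pipelines and model
selection.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import model as _model
from . import search as _search
from . import training as _training
from .masking import RepeatMask
from .model import ModelConfig, Sequence
from .training import TrainingConfig, TrainingPair


def _as_sequences(X: Iterable) -> list[Sequence]:
    seqs = []
    for i, item in enumerate(X):
        if isinstance(item, Sequence):
            seqs.append(item)
        elif isinstance(item, str):
            seqs.append(Sequence(f"seq{i}", item))
        else:
            raise TypeError(f"expected Sequence or str, got {type(item).__name__}")
    return seqs


class ResidueEmbedder(TransformerMixin, BaseEstimator):
    """Contrastively trained per-residue embedding transformer.

    Parameters mirror the architecture (embed_dim, n_blocks, kernel_size) and
    the training recipe (steps, batch_size, crop_len, learning_rate,
    weight_decay, gamma).  ``fit`` expects an iterable of
    :class:`~embfilter.training.TrainingPair` (two sequences plus their
    trusted alignment, optional repeat masks); ``transform`` maps sequences
    (or plain strings) to a list of (n_residues, embed_dim) arrays.

    Attributes
    ----------
    config_ : ModelConfig
    params_ : dict of weight arrays
    history_ : list of TrainingRecord (per optimization step)
    n_parameters_ : int
    """

    def __init__(self, embed_dim=256, n_blocks=8, kernel_size=7,
                 steps=24000, batch_size=512, crop_len=256,
                 learning_rate=1e-5, weight_decay=1e-2, gamma=5e-3,
                 symmetrized=False, random_state=0):
        self.embed_dim = embed_dim
        self.n_blocks = n_blocks
        self.kernel_size = kernel_size
        self.steps = steps
        self.batch_size = batch_size
        self.crop_len = crop_len
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.gamma = gamma
        self.symmetrized = symmetrized
        self.random_state = random_state

    def _configs(self) -> tuple[ModelConfig, TrainingConfig]:
        model_cfg = ModelConfig(embed_dim=self.embed_dim, n_blocks=self.n_blocks,
                                kernel_size=self.kernel_size)
        train_cfg = TrainingConfig(steps=self.steps, batch_size=self.batch_size,
                                   crop_len=self.crop_len,
                                   learning_rate=self.learning_rate,
                                   weight_decay=self.weight_decay, gamma=self.gamma,
                                   symmetrized=self.symmetrized,
                                   seed=self.random_state)
        return model_cfg, train_cfg

    def fit(self, X: TypingSequence[TrainingPair], y=None):
        """Train on aligned homolog pairs (y is ignored, sklearn-style)."""
        model_cfg, train_cfg = self._configs()
        init = _model.init_params(model_cfg, np.random.default_rng(self.random_state))
        pairs = list(X)
        self.params_, self.history_ = _training.train(init, pairs, train_cfg, model_cfg)
        self.config_ = model_cfg
        self.n_parameters_ = _model.count_parameters(model_cfg)
        return self

    def transform(self, X: Iterable) -> list[np.ndarray]:
        check_is_fitted(self, "params_")
        return [_model.encode_sequence(s, self.params_, self.config_)
                for s in _as_sequences(X)]

    def embed_named(self, seqs: Iterable[Sequence]) -> dict[str, np.ndarray]:
        """Like transform but keyed by sequence id."""
        check_is_fitted(self, "params_")
        return {s.id: _model.encode_sequence(s, self.params_, self.config_)
                for s in _as_sequences(seqs)}

    @classmethod
    def from_params(cls, config: ModelConfig, params: dict, **kwargs) -> "ResidueEmbedder":
        """Wrap existing weights (e.g. loaded from disk) as a fitted estimator."""
        _model.validate_params(config, params)
        est = cls(embed_dim=config.embed_dim, n_blocks=config.n_blocks,
                  kernel_size=config.kernel_size, **kwargs)
        est.config_ = config
        est.params_ = params
        est.history_ = []
        est.n_parameters_ = _model.count_parameters(config)
        return est


class ResiduePrefilter(BaseEstimator):
    """Homology-search pre-filter: fit on targets, rank targets per query.

    ``fit(targets)`` embeds and indexes the target set; ``search(queries)``
    returns a hits DataFrame (query_id, target_id, score, n_matches) sorted
    by query then score descending.  ``reversed`` indexes the queries instead
    and streams target residues against them; output keys are unchanged.
    """

    def __init__(self, embedder: ResidueEmbedder | None = None, k=150, delta=3.0,
                 backend="exact", reversed=False, gate_exponent=0.5):
        self.embedder = embedder
        self.k = k
        self.delta = delta
        self.backend = backend
        self.reversed = reversed
        self.gate_exponent = gate_exponent

    def _search_config(self) -> _search.SearchConfig:
        return _search.SearchConfig(k=self.k, delta=self.delta, backend=self.backend,
                                    reversed=self.reversed, d=self.embedder.config_.embed_dim,
                                    gate_exponent=self.gate_exponent)

    def fit(self, X: Iterable[Sequence], y=None,
            masks: Mapping[str, RepeatMask] | None = None):
        if self.embedder is None or not hasattr(self.embedder, "params_"):
            raise ValueError("ResiduePrefilter needs a fitted ResidueEmbedder")
        self.targets_ = _as_sequences(X)
        self.target_masks_ = masks
        self.target_embeddings_ = self.embedder.embed_named(self.targets_)
        return self

    def search(self, queries: Iterable[Sequence],
               masks: Mapping[str, RepeatMask] | None = None) -> pd.DataFrame:
        check_is_fitted(self, "targets_")
        queries = _as_sequences(queries)
        hits = _search.search(
            queries, self.targets_,
            self.embedder.params_, self.embedder.config_,
            cfg=self._search_config(),
            query_masks=masks, target_masks=self.target_masks_,
            target_embeddings=self.target_embeddings_,
        )
        return pd.DataFrame(
            [(h.query_id, h.target_id, h.score, h.n_matches) for h in hits],
            columns=["query_id", "target_id", "score", "n_matches"],
        )

    def transform(self, queries: Iterable[Sequence]) -> pd.DataFrame:
        """Alias for :meth:`search` so the estimator drops into pipelines."""
        return self.search(queries)
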