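"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the message-passing network needs: affine
maps, ReLU, row gather/scatter (segment sums for edge→atom aggregation),
concatenation, pooling, and the two training losses.  Gradients are exact and
are verified against central finite differences in the test suite.

Memory discipline matters more than it may seem: a training step churns
hundreds of MB-sized arrays, and general-purpose allocation of that pattern
fragments the heap badly (ever-growing RSS, page-fault-dominated step
times).  Gradient-tracked ops therefore draw their output buffers from an
exact-shape buffer pool; :meth:`Tensor.backward` dismantles the graph and
returns every intermediate buffer to the pool, so steady-state training
performs essentially no allocation.  Inference (``no_grad``) bypasses the
pool entirely.

Arrays default to float32 for training throughput; the graph respects the
dtype of its inputs so float64 can be used when checking gradients.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class _BufferPool:
    """Size-bucketed recycling pool for op output buffers.

    Buffers are flat arrays whose lengths are rounded up to coarse buckets;
    ``empty`` hands out a reshaped view of a recycled flat buffer.  Bucketing
    matters: graph batches all have slightly different edge counts, and an
    exact-shape pool would hoard a separate buffer set per batch instead of
    reusing one working set across the whole epoch.
    """

    _GRAIN = 1 << 18  # elements; ~1 MB of float32 per bucket step

    def __init__(self):
        self._free: dict[tuple, list] = {}

    def _bucket(self, size: int) -> int:
        if size >= self._GRAIN:
            return -(-size // self._GRAIN) * self._GRAIN
        b = 256
        while b < size:
            b <<= 1
        return b

    def empty(self, shape, dtype) -> np.ndarray:
        if not _grad_enabled:
            return np.empty(shape, dtype)
        shape = (shape,) if isinstance(shape, int) else tuple(shape)
        size = int(np.prod(shape)) if shape else 1
        lst = self._free.get((np.dtype(dtype).str, self._bucket(size)))
        if lst:
            return lst.pop()[:size].reshape(shape)
        return np.empty(self._bucket(size), dtype)[:size].reshape(shape)

    def zeros(self, shape, dtype) -> np.ndarray:
        buf = self.empty(shape, dtype)
        buf[...] = 0
        return buf

    def recycle(self, arr):
        if not isinstance(arr, np.ndarray) or arr.nbytes < 1024:
            return
        root = arr
        while isinstance(root, np.ndarray) and root.base is not None:
            root = root.base
        if (
            isinstance(root, np.ndarray)
            and root.base is None
            and root.flags.owndata
            and root.ndim == 1
            and root.size == self._bucket(arr.size)
            and root.dtype == arr.dtype
        ):
            self._free.setdefault((root.dtype.str, root.size), []).append(root)

    def clear(self):
        self._free.clear()


pool = _BufferPool()


def _pmm(a, b):
    """Matmul into a pooled output buffer."""
    out = pool.empty((a.shape[0], b.shape[1]), np.result_type(a, b))
    np.matmul(a, b, out=out)
    return out


class SegmentPlan:
    """Precomputed sort order for fast repeated segment sums over fixed indices.

    ``np.ufunc.at`` is an order of magnitude slower than gathering the rows in
    segment-sorted order and reducing contiguous runs with ``reduceat``; a
    plan amortizes the sort across every use of one index vector (e.g. the
    edge→atom map of a graph batch reused for all epochs).
    """

    def __init__(self, idx, n_segments: int):
        self.idx = np.asarray(idx, dtype=np.int64)
        self.n_segments = int(n_segments)
        self.order = np.argsort(self.idx, kind="stable")
        sorted_idx = self.idx[self.order]
        if sorted_idx.size:
            self.uniq, self.starts = np.unique(sorted_idx, return_index=True)
        else:
            self.uniq = np.zeros(0, dtype=np.int64)
            self.starts = np.zeros(0, dtype=np.int64)

    def sum_into(self, x: np.ndarray, out: np.ndarray) -> np.ndarray:
        """out[s] = sum of x rows whose index is s; out is overwritten."""
        out[...] = 0
        if not self.order.size:
            return out
        xs = pool.empty((self.order.size,) + x.shape[1:], x.dtype)
        np.take(x, self.order, axis=0, out=xs)
        seg = pool.empty((self.starts.size,) + x.shape[1:], x.dtype)
        np.add.reduceat(xs, self.starts, axis=0, out=seg)
        pool.recycle(xs)
        out[self.uniq] = seg
        pool.recycle(seg)
        return out


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g, own=False):
        """Add ``g`` into the gradient; ``own=True`` promises ``g`` is a
        freshly allocated array this tensor may adopt without copying."""
        if self.grad is None:
            if own and isinstance(g, np.ndarray) and g.dtype == self.data.dtype:
                self.grad = g
            else:
                buf = pool.empty(self.data.shape, self.data.dtype)
                np.copyto(buf, g)
                self.grad = buf
        else:
            self.grad += g
            if own:
                pool.recycle(g)

    def backward(self, free_graph=True):
        """Reverse-mode sweep from this (scalar) tensor.

        With ``free_graph`` (default) the graph is dismantled afterwards and
        every intermediate buffer (op outputs and their gradients — never
        leaves, parameters or constants) is returned to the buffer pool.
        """
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
        if free_graph:
            for t in topo:
                if t._backward is not None and t is not self:
                    pool.recycle(t.data)
                    pool.recycle(t.grad)
                    t.data = None
                    t.grad = None
                t._parents = ()
                t._backward = None

    def __repr__(self):
        shape = None if self.data is None else self.data.shape
        return f"Tensor(shape={shape}, grad={self.requires_grad})"


def _make(data, parents, backward):
    if _grad_enabled and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return Tensor(data)


def _finish(out, backward):
    if out.requires_grad:
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    out_data = pool.empty((x.data.shape[0], w.data.shape[1]),
                          np.result_type(x.data, w.data))
    np.matmul(x.data, w.data, out=out_data)
    out = _make(out_data, (x, w), None)

    def backward():
        if x.requires_grad:
            x._accumulate(_pmm(out.grad, w.data.T), own=True)
        if w.requires_grad:
            w._accumulate(_pmm(x.data.T, out.grad), own=True)

    return _finish(out, backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    """Elementwise add; supports broadcasting a bias row over rows."""
    shape = np.broadcast_shapes(x.data.shape, y.data.shape)
    out_data = pool.empty(shape, np.result_type(x.data, y.data))
    np.add(x.data, y.data, out=out_data)
    out = _make(out_data, (x, y), None)

    def backward():
        for t in (x, y):
            if t.requires_grad:
                g = out.grad
                if t.data.shape != g.shape:
                    g = _unbroadcast(g, t.data.shape)
                t._accumulate(g)

    return _finish(out, backward)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def scale(x: Tensor, c: float) -> Tensor:
    out = _make(x.data * c, (x,), None)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * c, own=True)

    return _finish(out, backward)


def sub(x: Tensor, y: Tensor) -> Tensor:
    return add(x, scale(y, -1.0))


def relu(x: Tensor) -> Tensor:
    out_data = pool.empty(x.data.shape, x.data.dtype)
    np.maximum(x.data, 0, out=out_data)
    out = _make(out_data, (x,), None)

    def backward():
        if x.requires_grad:
            g = pool.empty(out.grad.shape, out.grad.dtype)
            np.multiply(out.grad, out.data > 0, out=g)
            x._accumulate(g, own=True)

    return _finish(out, backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    return add(matmul(x, w), b)


def affine2(x1: Tensor, w1: Tensor, x2: Tensor, w2: Tensor, b: Tensor) -> Tensor:
    """Fused ``x1 @ w1 + x2 @ w2 + b``.

    Mathematically identical to a single affine map on ``[x1 ++ x2]`` with
    the stacked weight ``[w1; w2]``, but avoids materializing the
    concatenation (the hot path of the edge update).
    """
    out_data = pool.empty((x1.data.shape[0], w1.data.shape[1]), x1.data.dtype)
    np.matmul(x1.data, w1.data, out=out_data)
    tmp = pool.empty(out_data.shape, out_data.dtype)
    np.matmul(x2.data, w2.data, out=tmp)
    out_data += tmp
    pool.recycle(tmp)
    out_data += b.data
    out = _make(out_data, (x1, w1, x2, w2, b), None)

    def backward():
        g = out.grad
        if x1.requires_grad:
            x1._accumulate(_pmm(g, w1.data.T), own=True)
        if w1.requires_grad:
            w1._accumulate(_pmm(x1.data.T, g), own=True)
        if x2.requires_grad:
            x2._accumulate(_pmm(g, w2.data.T), own=True)
        if w2.requires_grad:
            w2._accumulate(_pmm(x2.data.T, g), own=True)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0), own=True)

    return _finish(out, backward)


def concat(tensors, axis=1) -> Tensor:
    datas = [t.data for t in tensors]
    out = _make(np.concatenate(datas, axis=axis), tuple(tensors), None)
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    def backward():
        parts = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(g)

    return _finish(out, backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    out_data = pool.empty((len(idx),) + x.data.shape[1:], x.data.dtype)
    np.take(x.data, idx, axis=0, out=out_data)
    out = _make(out_data, (x,), None)

    def backward():
        if x.requires_grad:
            g = pool.zeros(x.data.shape, x.data.dtype)
            np.add.at(g, idx, out.grad)
            x._accumulate(g, own=True)

    return _finish(out, backward)


def gather_sub(x: Tensor, idx: np.ndarray, y: Tensor, perm: np.ndarray,
               scatter_plan: SegmentPlan | None = None) -> Tensor:
    """Fused ``x[idx] - y[perm]`` (the "all incoming minus reverse" message)."""
    out_data = pool.empty((len(idx),) + x.data.shape[1:], x.data.dtype)
    np.take(x.data, idx, axis=0, out=out_data)
    tmp = pool.empty(out_data.shape, out_data.dtype)
    np.take(y.data, perm, axis=0, out=tmp)
    out_data -= tmp
    pool.recycle(tmp)
    out = _make(out_data, (x, y), None)

    def backward():
        g = out.grad
        if x.requires_grad:
            gx = pool.empty(x.data.shape, x.data.dtype)
            if scatter_plan is not None:
                scatter_plan.sum_into(g, gx)
            else:
                gx[...] = 0
                np.add.at(gx, idx, g)
            x._accumulate(gx, own=True)
        if y.requires_grad:
            gy = pool.empty((len(perm),) + y.data.shape[1:], y.data.dtype)
            np.take(g, perm, axis=0, out=gy)  # perm is an involution
            np.negative(gy, out=gy)
            y._accumulate(gy, own=True)

    return _finish(out, backward)


def permute_rows(x: Tensor, perm: np.ndarray) -> Tensor:
    """Row gather by a self-inverse permutation (the reverse-edge map)."""
    out_data = pool.empty(x.data.shape, x.data.dtype)
    np.take(x.data, perm, axis=0, out=out_data)
    out = _make(out_data, (x,), None)

    def backward():
        if x.requires_grad:
            g = pool.empty(out.grad.shape, out.grad.dtype)
            np.take(out.grad, perm, axis=0, out=g)
            x._accumulate(g, own=True)

    return _finish(out, backward)


def segment_sum(x: Tensor, idx: np.ndarray, n_segments: int,
                plan: SegmentPlan | None = None) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` bins given by ``idx``."""
    data = pool.empty((n_segments,) + x.data.shape[1:], x.data.dtype)
    if plan is not None:
        plan.sum_into(x.data, data)
    else:
        data[...] = 0
        np.add.at(data, idx, x.data)
    out = _make(data, (x,), None)

    def backward():
        if x.requires_grad:
            g = pool.empty((len(idx),) + out.grad.shape[1:], out.grad.dtype)
            np.take(out.grad, idx, axis=0, out=g)
            x._accumulate(g, own=True)

    return _finish(out, backward)


def segment_mean(x: Tensor, idx: np.ndarray, n_segments: int,
                 plan: SegmentPlan | None = None) -> Tensor:
    counts = np.bincount(idx, minlength=n_segments).astype(x.data.dtype)
    counts = np.maximum(counts, 1)[:, None]
    s = segment_sum(x, idx, n_segments, plan)
    out = _make(s.data / counts, (s,), None)

    def backward():
        if s.requires_grad:
            s._accumulate(out.grad / counts, own=True)

    return _finish(out, backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    if p <= 0 or not _grad_enabled:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = _make(x.data * mask, (x,), None)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * mask, own=True)

    return _finish(out, backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,), None)

    def backward():
        if x.requires_grad:
            x._accumulate(out.grad * s * (1.0 - s), own=True)

    return _finish(out, backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy, numerically stable in the logits."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = _make(np.array(loss.mean(), dtype=z.dtype), (logits,), None)

    def backward():
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-z))
            logits._accumulate(out.grad * (p - t) / t.size, own=True)

    return _finish(out, backward)


def mse(pred: Tensor, targets: np.ndarray) -> Tensor:
    t = np.asarray(targets, dtype=pred.data.dtype)
    diff = pred.data - t
    out = _make(np.array((diff * diff).mean(), dtype=pred.data.dtype), (pred,), None)

    def backward():
        if pred.requires_grad:
            pred._accumulate(out.grad * 2.0 * diff / diff.size, own=True)

    return _finish(out, backward)


class Adam:
    """Adam optimizer with optional global gradient-norm clipping.

    Update arithmetic runs in preallocated scratch buffers so optimizer steps
    allocate nothing.
    """

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, clip_norm=10.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self._scratch = [np.empty_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            if p.grad is not None:
                pool.recycle(p.grad)
            p.grad = None

    def step(self):
        self.t += 1
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        clip = 1.0
        if self.clip_norm is not None:
            total = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
            if total > self.clip_norm:
                clip = self.clip_norm / total
        c1 = 1 - self.b1 ** self.t
        c2 = 1 - self.b2 ** self.t
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._scratch):
            m *= self.b1
            m += (1 - self.b1) * clip * g
            v *= self.b2
            np.multiply(g, g, out=buf)
            v += (1 - self.b2) * clip * clip * buf
            np.sqrt(v / c2, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            p.data -= (self.lr / c1) * buf
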