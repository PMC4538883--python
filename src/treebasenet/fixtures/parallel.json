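{
 "format": "treebase-net-v1",
 "name": "parallel",
 "comment": "Smallest network with parallel arcs: one leaf, one reticulation w reached twice from u; legal because two attachment points adjacent in the support tree may carry a linking arc.",
 "vertices": [
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "rho"
  },
  {
   "id": "u"
  },
  {
   "id": "w"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "u"
  },
  {
   "id": "e01",
   "source": "u",
   "target": "w"
  },
  {
   "id": "e02",
   "source": "u",
   "target": "w"
  },
  {
   "id": "e03",
   "source": "w",
   "target": "a"
  }
 ]
}
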