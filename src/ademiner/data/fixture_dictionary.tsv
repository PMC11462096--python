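しびれ	末梢神経障害
しびれ感	末梢神経障害
ぴりぴり	末梢神経障害
ビリビリ	末梢神経障害
末梢神経障害	末梢神経障害
感覚異常	末梢神経障害
感覚の異常	末梢神経障害
痛覚低下	末梢神経障害
麻痺	麻痺
浮腫	浮腫
蜂窩織炎	蜂窩織炎
倦怠感	倦怠感
食欲低下	食欲低下
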