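"sex","age_group","contrast","estimate","SE","df","t.ratio","p.value"
"female",".","aged - young","1.132347048835427","0.283366692564078","6","3.996048507286614","0.00715110195641132"
"male",".","aged - young","1.043286450147854","0.262447928918368","6","3.975213119217865","0.00732318576886191"
".","young","male - female","0.270673281799460","0.309858580240505","6","0.873538120485062","0.41595800375915781"
".","aged","male - female","0.181612683111887","0.303376356499716","6","0.598638223516461","0.57130673522513331"
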