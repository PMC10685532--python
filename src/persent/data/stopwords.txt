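و
در
به
از
که
را
با
برای
این
آن
است
بود
شد
هست
نیست
هم
تا
یا
اگر
ولی
اما
چون
چه
هر
ما
من
او
شما
آنها
خود
دیگر
یک
دو
هیچ
همه
باید
شاید
وقتی
پس
روی
زیر
بین
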